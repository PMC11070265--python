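"""JSDM model object, penalized fitting, prediction and serialization."""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import ndtr, ndtri

from .likelihood import mc_probit_nll
from .networks import LinearNet, MLPNet, make_network, _rowwise_matmul
from .trend import TrendSurface, build_trend_surface

__all__ = ["Hyperparameters", "JSDMModel", "fit"]

# fixed zip timestamp so model archives are byte-stable across reruns
_ZIP_DATE = (1980, 1, 1, 0, 0, 0)


@dataclass
class Hyperparameters:
    """Penalty structure, latent rank, architecture and optimizer budget.

    Elastic-net penalties apply separately to the environment weights,
    the trend-surface coefficients and the species loadings; each block
    has a strength (``*_penalty`` >= 0) and an L1/L2 mix (``*_mix`` in
    [0, 1]; 1 = pure lasso). Biases are never penalized.
    """

    env_penalty: float = 0.001
    env_mix: float = 0.5
    trend_penalty: float = 0.001
    trend_mix: float = 0.5
    loading_penalty: float = 0.001
    loading_mix: float = 0.5
    latent_rank: int = 2
    hidden: tuple[int, ...] = ()
    trend_degree: int = 2
    lr: float = 0.05
    epochs: int = 500
    mc_draws: int = 100

    def __post_init__(self) -> None:
        self.hidden = tuple(int(h) for h in self.hidden)
        for name in ("env_penalty", "trend_penalty", "loading_penalty"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("env_mix", "trend_mix", "loading_mix"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.latent_rank < 0:
            raise ValueError("latent_rank must be >= 0")
        if self.mc_draws < 1:
            raise ValueError("mc_draws must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")

    @property
    def total_penalty(self) -> float:
        return self.env_penalty + self.trend_penalty + self.loading_penalty

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden"] = list(self.hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparameters":
        d = dict(d)
        d["hidden"] = tuple(d.get("hidden", ()))
        return cls(**d)


@dataclass
class JSDMModel:
    """A fitted joint species distribution model.

    Holds the environment network, species loadings, trend surface and
    the training standardization parameters needed to score new sites
    or raster pixels.
    """

    net: LinearNet | MLPNet
    loadings: np.ndarray
    trend: TrendSurface
    trend_coef: np.ndarray
    hyper: Hyperparameters
    covariate_names: list[str]
    species_ids: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    seed: int = 0
    training_log: list[float] = field(default_factory=list)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def latent_rank(self) -> int:
        return self.loadings.shape[1]

    def _check_schema(self, covariate_names) -> None:
        if covariate_names is None:
            return
        if list(covariate_names) != list(self.covariate_names):
            missing = sorted(set(self.covariate_names) - set(covariate_names))
            extra = sorted(set(covariate_names) - set(self.covariate_names))
            raise ValueError(
                f"covariate schema mismatch: missing {missing}, unexpected {extra}"
            )

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) / self.x_sd

    def linear_predictor(
        self,
        X: np.ndarray,
        coords: np.ndarray,
        covariate_names=None,
        rowwise: bool = False,
    ) -> np.ndarray:
        """Latent-scale eta (env net + trend), before the latent factors.

        ``rowwise=True`` uses batch-size-independent accumulation so the
        result is bit-identical however the rows are chunked.
        """
        self._check_schema(covariate_names)
        Xs = self.standardize(X)
        B = self.trend.transform(np.asarray(coords, dtype=float))
        if rowwise:
            return self.net.rowwise_forward(Xs) + _rowwise_matmul(B, self.trend_coef)
        return self.net.forward(Xs) + B @ self.trend_coef

    def predict_prob(
        self,
        X: np.ndarray,
        coords: np.ndarray,
        covariate_names=None,
        rowwise: bool = False,
    ) -> np.ndarray:
        """Marginal occurrence probabilities Phi(eta / sqrt(1 + ||Lambda_j||^2))."""
        eta = self.linear_predictor(X, coords, covariate_names, rowwise=rowwise)
        scale = np.sqrt(1.0 + np.sum(self.loadings**2, axis=1))
        return ndtr(eta / scale)

    def nll(self, X, coords, Y, n_draws: int | None = None, seed: int = 0) -> float:
        """MC probit NLL of data under this model (no penalties)."""
        eta = self.linear_predictor(X, coords)
        M = n_draws if n_draws is not None else self.hyper.mc_draws
        loadings = self.loadings if self.latent_rank > 0 else None
        return mc_probit_nll(eta, np.asarray(Y, dtype=float), loadings, n_draws=M, seed=seed)

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        """Single-archive format: meta.json + raw .npy members in a zip."""
        arrays = {"loadings": self.loadings, "trend_coef": self.trend_coef,
                  "x_mean": self.x_mean, "x_sd": self.x_sd,
                  "coord_mean": self.trend.coord_mean, "coord_sd": self.trend.coord_sd,
                  "training_log": np.asarray(self.training_log, dtype=float)}
        for key, arr in self.net.params().items():
            arrays[f"net_{key}"] = arr
        meta = {
            "format": "biodivmap-jsdm-1",
            "net_kind": self.net.kind,
            "hidden": list(self.net.hidden_sizes),
            "hyper": self.hyper.to_dict(),
            "covariate_names": list(self.covariate_names),
            "species_ids": list(self.species_ids),
            "trend_degree": self.trend.degree,
            "trend_basis_names": list(self.trend.basis_names),
            "seed": self.seed,
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            info = zipfile.ZipInfo("meta.json", date_time=_ZIP_DATE)
            zf.writestr(info, json.dumps(meta, indent=1, sort_keys=True))
            for name in sorted(arrays):
                buf = io.BytesIO()
                np.lib.format.write_array(buf, np.ascontiguousarray(arrays[name]))
                info = zipfile.ZipInfo(f"{name}.npy", date_time=_ZIP_DATE)
                zf.writestr(info, buf.getvalue())

    @classmethod
    def load(cls, path) -> "JSDMModel":
        with zipfile.ZipFile(path, "r") as zf:
            meta = json.loads(zf.read("meta.json"))
            arrays = {}
            for name in zf.namelist():
                if name.endswith(".npy"):
                    arrays[name[:-4]] = np.lib.format.read_array(io.BytesIO(zf.read(name)))
        hyper = Hyperparameters.from_dict(meta["hyper"])
        if meta["net_kind"] == "linear":
            net = LinearNet(arrays["net_W"], arrays["net_b"])
        else:
            n_layers = len(meta["hidden"]) + 1
            net = MLPNet(
                [arrays[f"net_W{i}"] for i in range(n_layers)],
                [arrays[f"net_b{i}"] for i in range(n_layers)],
            )
        trend = TrendSurface(
            degree=meta["trend_degree"],
            coord_mean=arrays["coord_mean"],
            coord_sd=arrays["coord_sd"],
            basis_names=list(meta["trend_basis_names"]),
        )
        return cls(
            net=net,
            loadings=arrays["loadings"],
            trend=trend,
            trend_coef=arrays["trend_coef"],
            hyper=hyper,
            covariate_names=list(meta["covariate_names"]),
            species_ids=list(meta["species_ids"]),
            x_mean=arrays["x_mean"],
            x_sd=arrays["x_sd"],
            seed=meta["seed"],
            training_log=arrays["training_log"].tolist(),
        )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


class _Adam:
    """Adam on the smooth loss; penalties are applied separately by
    proximal shrinkage so heavily penalized blocks reach exactly zero."""

    def __init__(self, params: dict[str, np.ndarray]):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float) -> dict[str, np.ndarray]:
        """Update params in place; return the per-coordinate effective step
        sizes, needed by the proximal penalty update."""
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        steps: dict[str, np.ndarray] = {}
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            steps[k] = lr / (np.sqrt(vhat) + eps)
            params[k] -= steps[k] * mhat
        return steps


def _elastic_net_value(w: np.ndarray, strength: float, mix: float) -> float:
    if strength == 0:
        return 0.0
    return float(strength * (mix * np.abs(w).sum() + 0.5 * (1 - mix) * np.sum(w**2)))


def _elastic_net_prox(w: np.ndarray, strength: float, mix: float,
                      step: np.ndarray) -> np.ndarray:
    """Proximal operator of the elastic net (in place).

    ``step`` is the per-coordinate effective step size of the preceding
    gradient update (proximal-Adam), so the combined update's fixed
    point solves the penalized stationarity condition exactly and fully
    shrunk blocks reach literal zero.
    """
    if strength == 0:
        return w
    w /= 1.0 + step * strength * (1.0 - mix)
    if mix > 0:
        thresh = step * strength * mix
        np.copyto(w, np.sign(w) * np.maximum(np.abs(w) - thresh, 0.0))
    return w


def _coerce_training_data(Y, X, coords):
    """Accept (IncidenceMatrix, CovariateTable) or raw arrays."""
    species_ids = covariate_names = None
    if hasattr(Y, "values") and hasattr(Y, "species_ids"):
        species_ids = list(Y.species_ids)
        if coords is None and Y.x is not None:
            coords = Y.coords
        Y = Y.values
    if hasattr(X, "values") and hasattr(X, "covariate_names"):
        covariate_names = list(X.covariate_names)
        X = X.values
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if coords is None:
        raise ValueError("coords are required (none supplied or attached)")
    coords = np.asarray(coords, dtype=float)
    if species_ids is None:
        species_ids = [f"sp_{j + 1:03d}" for j in range(Y.shape[1])]
    if covariate_names is None:
        covariate_names = [f"cov_{k + 1:02d}" for k in range(X.shape[1])]
    return Y, X, coords, species_ids, covariate_names


def fit(Y, X, coords=None, hyper: Hyperparameters | None = None, seed: int = 0) -> JSDMModel:
    """Fit the penalized MC-probit JSDM by full-batch Adam.

    Deterministic given (data, hyper, seed): latent draws are sampled
    once up front (common random numbers) and the optimizer is
    single-threaded full-batch gradient descent with early stopping on a
    training-loss plateau.
    """
    hyper = hyper if hyper is not None else Hyperparameters()
    Y, Xv, coords, species_ids, covariate_names = _coerce_training_data(Y, X, coords)
    n, S = Y.shape
    if S < 2:
        raise ValueError("need >= 2 species for a joint model")
    if Xv.shape[0] != n or coords.shape[0] != n:
        raise ValueError("Y, X and coords disagree on sample count")
    if np.isnan(Xv).any():
        raise ValueError("missing values in covariates")
    if not np.all((Y == 0) | (Y == 1)):
        raise ValueError("Y must be binary")

    x_mean = Xv.mean(axis=0)
    x_sd = np.where(Xv.std(axis=0) == 0, 1.0, Xv.std(axis=0))
    Xs = (Xv - x_mean) / x_sd
    trend = build_trend_surface(coords, degree=hyper.trend_degree)
    B = trend.transform(coords)

    rng = np.random.default_rng(seed)
    prevalence = np.clip(Y.mean(axis=0), 1.0 / (n + 1), n / (n + 1.0))
    net = make_network(Xs.shape[1], S, hyper.hidden, rng, bias=ndtri(prevalence))
    r = hyper.latent_rank
    loadings = 0.1 * rng.standard_normal((S, r)) if r > 0 else np.zeros((S, 0))
    trend_coef = np.zeros((trend.n_basis, S))
    draws = rng.standard_normal((hyper.mc_draws, r)) if r > 0 else None

    params: dict[str, np.ndarray] = {f"net_{k}": v for k, v in net.params().items()}
    params["trend_coef"] = trend_coef
    if r > 0:
        params["loadings"] = loadings
    opt = _Adam(params)
    env_weight_keys = [f"net_{k}" for k in net.weight_keys()]
    penalized = [(key, hyper.env_penalty, hyper.env_mix) for key in env_weight_keys]
    penalized.append(("trend_coef", hyper.trend_penalty, hyper.trend_mix))
    if r > 0:
        penalized.append(("loadings", hyper.loading_penalty, hyper.loading_mix))

    log: list[float] = []
    best = np.inf
    plateau = 0
    for epoch in range(hyper.epochs):
        # exponential decay to 1% of the initial rate over the epoch budget
        lr = hyper.lr * 0.01 ** (epoch / max(hyper.epochs - 1, 1))
        eta = net.forward(Xs) + B @ params["trend_coef"]
        nll, d_eta, d_load = mc_probit_nll(
            eta, Y, params.get("loadings") if r > 0 else None,
            draws=draws, return_grads=True,
        )
        loss = nll / n + sum(
            _elastic_net_value(params[key], strength, mix) for key, strength, mix in penalized
        )
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged (non-finite loss) at epoch {epoch} with {hyper.to_dict()}"
            )
        log.append(float(loss))
        d_eta = d_eta / n
        grads = {f"net_{k}": v for k, v in net.backward(d_eta).items()}
        grads["trend_coef"] = B.T @ d_eta
        if r > 0:
            grads["loadings"] = d_load / n
        steps = opt.step(params, grads, lr)
        for key, strength, mix in penalized:
            _elastic_net_prox(params[key], strength, mix, steps[key])
        # plateau-based early stop
        if loss < best - 1e-5:
            best = loss
            plateau = 0
        else:
            plateau += 1
            if plateau >= 50:
                break

    return JSDMModel(
        net=net,
        loadings=params.get("loadings", np.zeros((S, 0))),
        trend=trend,
        trend_coef=params["trend_coef"],
        hyper=hyper,
        covariate_names=covariate_names,
        species_ids=species_ids,
        x_mean=x_mean,
        x_sd=x_sd,
        seed=seed,
        training_log=log,
    )
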