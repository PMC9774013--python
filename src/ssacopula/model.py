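"""Hybrid deterministic-stochastic heart-rate forecaster.

The model splits an HR series into a smooth deterministic part, extracted and
extrapolated by singular spectrum analysis, and a stochastic residual
("anomaly"), whose serial dependence is captured by Archimedean pair copulas
fitted on a lagged residual matrix.  The forecast is the sum of the SSA trend
extrapolation and the copula conditional-mean residual prediction.

API shape follows the model/results convention: :class:`HybridHRForecaster`
is constructed from data and configuration; :meth:`HybridHRForecaster.fit`
returns a :class:`HybridHRResults` carrying all fitted state, with
``predict``, ``summary``, ``save``/``load``.  Sliding-origin evaluation lives
in :func:`evaluate`, producing a :class:`HorizonErrorTable` (mean absolute
error per forecast step in bpm).
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import ssa
from .copulas import (
    Copula,
    CopulaFitError,
    IndependenceCopula,
    fit_ml,
    gof_select,
    make_copula,
    pseudo_observations,
)
from .series import TimeSeries

__all__ = [
    "PredictorConfig",
    "EmpiricalMarginal",
    "ResidualLagMatrix",
    "HybridHRForecaster",
    "HybridHRResults",
    "HorizonErrorTable",
    "evaluate",
]

logger = logging.getLogger(__name__)

_DEGENERATE_TOL = 1e-12
_U_CLIP = 1e-9


@dataclass(frozen=True)
class PredictorConfig:
    """Configuration of the hybrid predictor.

    Defaults follow the reference analysis protocol: 1,500 training epochs
    sliding by 1, trend reconstructed from the leading 60 singular triples,
    residual lag matrix of window 30 with delay 1, 30-epoch horizon, and
    3,000 conditional draws per step.  The SSA window defaults to half the
    training window (750), the standard choice when no window is prescribed.
    """

    train_length: int = 1500
    slide_step: int = 1
    ssa_window: int = 750
    ssa_components: int = 60
    residual_window: int = 30
    residual_delay: int = 1
    horizon: int = 30
    n_conditional_samples: int = 3000
    seed: int = 0
    copula_family: str = "auto"  # auto | clayton | frank | gumbel | independence
    share_pair_copula: bool = False
    refit_every: int = 1
    clamp_output: bool = False
    amplitude_bounds: tuple = (25.0, 240.0)

    def __post_init__(self):
        if not (self.train_length > self.ssa_window > self.ssa_components >= 1):
            raise ValueError(
                "require train_length > ssa_window > ssa_components >= 1; got "
                f"{self.train_length} / {self.ssa_window} / {self.ssa_components}"
            )
        if self.horizon > self.residual_window:
            raise ValueError(
                f"horizon ({self.horizon}) must not exceed residual_window "
                f"({self.residual_window})"
            )
        if self.n_conditional_samples < 1:
            raise ValueError("n_conditional_samples must be >= 1")
        if self.residual_window < 2 or self.residual_delay < 1:
            raise ValueError("residual_window must be >= 2 and residual_delay >= 1")
        if self.slide_step < 1 or self.refit_every < 1:
            raise ValueError("slide_step and refit_every must be >= 1")
        if self.copula_family not in ("auto", "clayton", "frank", "gumbel", "independence"):
            raise ValueError(f"unknown copula_family {self.copula_family!r}")
        lo, hi = self.amplitude_bounds
        if not lo < hi:
            raise ValueError("amplitude_bounds must be an ordered (low, high) pair")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["amplitude_bounds"] = list(d["amplitude_bounds"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PredictorConfig":
        d = dict(d)
        if "amplitude_bounds" in d:
            d["amplitude_bounds"] = tuple(d["amplitude_bounds"])
        return cls(**d)

    def hash(self) -> str:
        """Stable short hash of the configuration, for run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


class EmpiricalMarginal:
    """Empirical marginal of one residual-matrix column.

    CDF places the sorted sample values at plotting positions
    ``i / (n + 1)`` with linear interpolation between them; the quantile
    function is the linear-interpolation inverse, clamped to the observed
    min/max (no extrapolation outside the sample range).
    """

    def __init__(self, values):
        xs = np.sort(np.asarray(values, dtype=float))
        if xs.size < 2:
            raise ValueError("marginal needs at least 2 values")
        self.xs = xs
        self.ps = np.arange(1, xs.size + 1) / (xs.size + 1.0)
        self.degenerate = bool(xs[-1] - xs[0] < _DEGENERATE_TOL)

    def cdf(self, x):
        if self.degenerate:
            return np.full_like(np.asarray(x, dtype=float), 0.5)
        out = np.interp(x, self.xs, self.ps)
        return np.clip(out, self.ps[0], self.ps[-1])

    def ppf(self, p):
        if self.degenerate:
            return np.full_like(np.asarray(p, dtype=float), self.xs[0])
        # np.interp clamps below ps[0] / above ps[-1] to the sample min/max
        return np.interp(p, self.ps, self.xs)


class ResidualLagMatrix:
    """Lagged matrix of SSA residuals with per-column empirical marginals.

    Column ``j`` (0-based) holds the residual series shifted by
    ``j * delay`` epochs, so adjacent columns are lag-``delay`` pairs of the
    same process; all columns share one length.
    """

    def __init__(self, residuals, window: int, delay: int = 1):
        res = np.asarray(getattr(residuals, "values", residuals), dtype=float)
        window = int(window)
        delay = int(delay)
        if window < 2 or delay < 1:
            raise ValueError("window must be >= 2 and delay >= 1")
        rows = res.size - (window - 1) * delay
        if rows < 2:
            raise ValueError(
                f"residual series too short: need at least {(window - 1) * delay + 2} "
                f"values for window {window} and delay {delay}, got {res.size}"
            )
        self.window = window
        self.delay = delay
        self.columns = np.stack(
            [res[j * delay : j * delay + rows] for j in range(window)], axis=1
        )
        self.marginals = [EmpiricalMarginal(self.columns[:, j]) for j in range(window)]

    @property
    def n_rows(self) -> int:
        return int(self.columns.shape[0])


def _fit_pair_copula(u, v, family: str):
    """Fit/select one pair copula; independence fallback on failure."""
    try:
        if family == "auto":
            gof = gof_select(u, v)
            return make_copula(gof.family, gof.theta), gof.distances.get(gof.family)
        if family == "independence":
            return IndependenceCopula(), None
        return make_copula(family, fit_ml(u, v, family)), None
    except (CopulaFitError, ValueError) as exc:
        logger.warning("pair-copula fit failed (%s); using independence", exc)
        return IndependenceCopula(), None


class HybridHRForecaster:
    """SSA + pair-copula hybrid model of a heart-rate series.

    Parameters
    ----------
    endog : array-like or TimeSeries or pandas.Series
        The observed series in bpm.  Fitting uses the last
        ``config.train_length`` epochs so forecasts continue the series end.
    config : PredictorConfig, optional
        Full configuration; individual fields may be overridden by keyword.
    """

    def __init__(self, endog, config: PredictorConfig | None = None, **overrides):
        if isinstance(endog, TimeSeries):
            self.series = endog
        elif isinstance(endog, pd.Series):
            self.series = TimeSeries(endog.to_numpy(dtype=float))
        else:
            self.series = TimeSeries(np.asarray(endog, dtype=float))
        base = config if config is not None else PredictorConfig()
        self.config = replace(base, **overrides) if overrides else base

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        value_col: str = "hr_bpm",
        config: PredictorConfig | None = None,
        **overrides,
    ) -> "HybridHRForecaster":
        if value_col not in frame.columns:
            raise KeyError(f"column {value_col!r} not found in frame")
        return cls(frame[value_col].to_numpy(dtype=float), config=config, **overrides)

    def fit(self) -> "HybridHRResults":
        cfg = self.config
        y = self.series.values
        if y.size < cfg.train_length:
            raise ValueError(
                f"series length {y.size} is shorter than train_length {cfg.train_length}"
            )
        train = y[-cfg.train_length :]

        X = ssa.embed(train, cfg.ssa_window)
        decomposition = ssa.decompose(X)
        # the requested component count may exceed the matrix's effective rank
        # (noise-free signals); use what exists
        n_components = min(cfg.ssa_components, decomposition.rank)
        trend_matrix, _ = ssa.group(decomposition, n_components)
        reconstruction = ssa.diagonal_average(trend_matrix)
        residuals = train - reconstruction
        recurrence, verticality = ssa.recurrence_coefficients(
            decomposition.left_vectors[:, :n_components]
        )

        lag_matrix = ResidualLagMatrix(residuals, cfg.residual_window, cfg.residual_delay)
        pair_copulas: list[Copula] = []
        pair_distances: list = []
        n_pairs = cfg.residual_window - 1
        if cfg.share_pair_copula:
            u = np.concatenate(
                [pseudo_observations(lag_matrix.columns[:, j], lag_matrix.columns[:, j + 1])[0]
                 for j in range(n_pairs)]
            )
            v = np.concatenate(
                [pseudo_observations(lag_matrix.columns[:, j], lag_matrix.columns[:, j + 1])[1]
                 for j in range(n_pairs)]
            )
            if np.ptp(lag_matrix.columns) < _DEGENERATE_TOL:
                shared, dist = IndependenceCopula(), None
            else:
                shared, dist = _fit_pair_copula(u, v, cfg.copula_family)
            pair_copulas = [shared] * n_pairs
            pair_distances = [dist] * n_pairs
            logger.info("pooled pair copula: %s theta=%.4g", shared.family, shared.theta)
        else:
            for j in range(n_pairs):
                cj = lag_matrix.columns[:, j]
                ck = lag_matrix.columns[:, j + 1]
                if np.ptp(cj) < _DEGENERATE_TOL or np.ptp(ck) < _DEGENERATE_TOL:
                    cop, dist = IndependenceCopula(), None
                    logger.info("pair (%d,%d): degenerate column, independence", j + 1, j + 2)
                else:
                    u, v = pseudo_observations(cj, ck)
                    cop, dist = _fit_pair_copula(u, v, cfg.copula_family)
                    logger.info(
                        "pair (%d,%d): family=%s theta=%.4g", j + 1, j + 2, cop.family, cop.theta
                    )
                pair_copulas.append(cop)
                pair_distances.append(dist)

        provenance = {
            "seed": cfg.seed,
            "config_hash": cfg.hash(),
            "package_version": _pkg_version,
            "fitted_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }
        return HybridHRResults(
            config=cfg,
            train=train,
            reconstruction=reconstruction,
            residuals=residuals,
            lag_matrix=lag_matrix,
            pair_copulas=pair_copulas,
            pair_distances=pair_distances,
            recurrence=recurrence,
            verticality=verticality,
            n_components=n_components,
            singular_values=decomposition.singular_values,
            provenance=provenance,
        )


@dataclass
class HybridHRResults:
    """Fitted hybrid model: SSA trend state plus residual pair copulas."""

    config: PredictorConfig
    train: np.ndarray
    reconstruction: np.ndarray
    residuals: np.ndarray
    lag_matrix: ResidualLagMatrix
    pair_copulas: list
    pair_distances: list
    recurrence: np.ndarray
    verticality: float
    n_components: int
    singular_values: np.ndarray
    provenance: dict = field(default_factory=dict)

    # ------------------------------------------------------------------ fit
    def forecast_deterministic(self, horizon: int) -> np.ndarray:
        """SSA trend extrapolation by the fitted linear recurrence."""
        L = self.config.ssa_window
        buf = np.concatenate([self.reconstruction[-(L - 1) :], np.empty(horizon)])
        for t in range(horizon):
            buf[L - 1 + t] = self.recurrence @ buf[t : L - 1 + t]
        return buf[L - 1 :].copy()

    def forecast_residual(self, horizon: int, rng=None) -> np.ndarray:
        """Chained one-step conditional-mean residual prediction.

        At step h the latest residual (observed for h = 1, predicted after)
        is mapped to rank space through the current column's marginal, the
        pair copula's conditional distribution is sampled
        ``n_conditional_samples`` times, each draw is mapped back through the
        next column's inverse marginal, and the sample mean becomes both the
        step-h prediction and the next conditioning value.
        """
        cfg = self.config
        if rng is None:
            rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
        W = cfg.residual_window
        out = np.empty(horizon)
        z = float(self.residuals[-1])
        for h in range(1, horizon + 1):
            pair = min(h, W - 1)  # 1-based pair index; last pair reused at h = W
            cop = self.pair_copulas[pair - 1]
            m_from = self.lag_matrix.marginals[pair - 1]
            m_to = self.lag_matrix.marginals[pair]
            u = float(np.clip(m_from.cdf(z), _U_CLIP, 1.0 - _U_CLIP))
            draws = cop.conditional_sample(u, cfg.n_conditional_samples, rng)
            z = float(np.mean(m_to.ppf(draws)))
            out[h - 1] = z
        return out

    def predict(self, horizon: int | None = None, rng=None, return_components: bool = False):
        """Hybrid forecast: SSA extrapolation plus residual prediction, per step.

        Deterministic for a fixed configuration seed (a fresh generator is
        derived from it on every call unless ``rng`` is supplied).
        """
        cfg = self.config
        h = cfg.horizon if horizon is None else int(horizon)
        if h < 1:
            raise ValueError("horizon must be >= 1")
        if h > cfg.residual_window:
            raise ValueError(
                f"horizon {h} exceeds residual_window {cfg.residual_window}"
            )
        det = self.forecast_deterministic(h)
        sto = self.forecast_residual(h, rng=rng)
        out = det + sto
        if cfg.clamp_output:
            out = np.clip(out, *cfg.amplitude_bounds)
        if return_components:
            return out, det, sto
        return out

    # ----------------------------------------------------------- diagnostics
    def summary(self) -> str:
        cfg = self.config
        fams = [c.family for c in self.pair_copulas]
        fam_counts = {f: fams.count(f) for f in sorted(set(fams))}
        sv = self.singular_values
        lines = [
            "Hybrid SSA + copula heart-rate model",
            "=" * 44,
            f"training epochs        {cfg.train_length}",
            f"SSA window / components {cfg.ssa_window} / {self.n_components}"
            + (f" (of {cfg.ssa_components} requested)" if self.n_components < cfg.ssa_components else ""),
            f"effective rank d       {sv.size}",
            f"leading singular value {sv[0]:.4g}" if sv.size else "leading singular value n/a",
            f"verticality nu^2       {self.verticality:.4g}",
            f"residual sd (bpm)      {np.std(self.residuals):.4g}",
            f"residual window/delay  {cfg.residual_window} / {cfg.residual_delay}",
            f"pair copulas           {len(self.pair_copulas)}"
            + (" (pooled)" if cfg.share_pair_copula else ""),
            f"families               {fam_counts}",
            f"conditional draws/step {cfg.n_conditional_samples}",
            f"seed                   {cfg.seed}",
            f"config hash            {self.provenance.get('config_hash', '')}",
        ]
        return "\n".join(lines)

    # ---------------------------------------------------------- persistence
    def save(self, path) -> None:
        """Serialize to a directory of plain-text files (YAML metadata + CSV)."""
        import pathlib

        import yaml

        d = pathlib.Path(path)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": self.config.to_dict(),
            "provenance": self.provenance,
            "n_components": self.n_components,
            "verticality": self.verticality,
            "pair_copulas": [c.to_dict() for c in self.pair_copulas],
            "pair_distances": [
                None if x is None else float(x) for x in self.pair_distances
            ],
        }
        (d / "model.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
        pd.DataFrame(
            {
                "train": self.train,
                "reconstruction": self.reconstruction,
                "residual": self.residuals,
            }
        ).to_csv(d / "state.csv", index=False)
        pd.DataFrame({"recurrence": self.recurrence}).to_csv(d / "recurrence.csv", index=False)
        pd.DataFrame({"singular_value": self.singular_values}).to_csv(
            d / "spectrum.csv", index=False
        )

    @classmethod
    def load(cls, path) -> "HybridHRResults":
        import pathlib

        import yaml

        d = pathlib.Path(path)
        meta = yaml.safe_load((d / "model.yaml").read_text())
        cfg = PredictorConfig.from_dict(meta["config"])
        state = pd.read_csv(d / "state.csv")
        residuals = state["residual"].to_numpy()
        return cls(
            config=cfg,
            train=state["train"].to_numpy(),
            reconstruction=state["reconstruction"].to_numpy(),
            residuals=residuals,
            lag_matrix=ResidualLagMatrix(residuals, cfg.residual_window, cfg.residual_delay),
            pair_copulas=[make_copula(c["family"], c["theta"]) for c in meta["pair_copulas"]],
            pair_distances=meta["pair_distances"],
            recurrence=pd.read_csv(d / "recurrence.csv")["recurrence"].to_numpy(),
            verticality=float(meta["verticality"]),
            n_components=int(meta["n_components"]),
            singular_values=pd.read_csv(d / "spectrum.csv")["singular_value"].to_numpy(),
            provenance=meta["provenance"],
        )


# ---------------------------------------------------------------------------
# sliding-origin evaluation
# ---------------------------------------------------------------------------


@dataclass
class HorizonErrorTable:
    """Mean absolute forecast error per horizon step, over sliding origins."""

    steps: np.ndarray
    mae: np.ndarray
    n_origins: int
    abs_errors: np.ndarray  # (n_origins, H) per-origin |error| matrix
    ssa_mae: np.ndarray | None = None  # deterministic-part-only MAE, if recorded

    def __post_init__(self):
        if self.n_origins < 1:
            raise ValueError("need at least one prediction origin")
        if np.any(self.mae < 0) or not np.all(np.isfinite(self.mae)):
            raise ValueError("MAE values must be finite and non-negative")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"step": self.steps, "mae_bpm": self.mae, "n_origins": self.n_origins}
        )
        if self.ssa_mae is not None:
            frame["mae_ssa_only_bpm"] = self.ssa_mae
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def evaluate(
    endog,
    config: PredictorConfig | None = None,
    max_origins: int | None = None,
    include_ssa_only: bool = True,
    predict_fn=None,
    **overrides,
) -> HorizonErrorTable:
    """Sliding-origin evaluation of the hybrid forecaster.

    The origin slides by ``slide_step`` across the series; at each origin the
    model is fitted on the preceding ``train_length`` epochs (full refit by
    default; see ``refit_every``), an ``horizon``-step forecast is issued, and
    absolute errors against the observed continuation are accumulated into
    per-step means.

    Parameters
    ----------
    max_origins : int, optional
        Evaluate at most this many origins (from the earliest).
    include_ssa_only : bool
        Also record the MAE of the deterministic (SSA-only) part.
    predict_fn : callable, optional
        ``predict_fn(y, origin, horizon) -> array`` replacing the hybrid
        forecast — a hook for oracle/uncertainty studies.
    """
    y = np.asarray(getattr(endog, "values", endog), dtype=float)
    base = config if config is not None else PredictorConfig()
    cfg = replace(base, **overrides) if overrides else base
    T, H = cfg.train_length, cfg.horizon
    if y.size < T + H + 1:
        raise ValueError(
            f"series length {y.size} too short for evaluation: need at least "
            f"train_length + horizon + 1 = {T + H + 1}"
        )
    origins = np.arange(T, y.size - H + 1, cfg.slide_step)
    if max_origins is not None:
        origins = origins[: int(max_origins)]

    abs_err = np.empty((origins.size, H))
    ssa_err = np.empty((origins.size, H)) if include_ssa_only else None
    model: HybridHRResults | None = None
    for i, p in enumerate(origins):
        truth = y[p : p + H]
        if predict_fn is not None:
            pred = np.asarray(predict_fn(y, int(p), H), dtype=float)
            abs_err[i] = np.abs(pred - truth)
            if ssa_err is not None:
                ssa_err[i] = abs_err[i]
            continue
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, int(p)]))
        if i % cfg.refit_every == 0 or model is None:
            model = HybridHRForecaster(y[:p], cfg).fit()
            pred, det, _ = model.predict(H, rng=rng, return_components=True)
        else:
            # reuse the stored recurrence and copulas; seed the recurrence
            # from the raw tail and approximate the conditioning residual by
            # a one-step recurrence estimate (speed/fidelity trade)
            L = cfg.ssa_window
            buf = np.concatenate([y[p - (L - 1) : p], np.empty(H)])
            for t in range(H):
                buf[L - 1 + t] = model.recurrence @ buf[t : L - 1 + t]
            det = buf[L - 1 :].copy()
            stale = model.residuals
            model.residuals = np.append(
                stale[1:], y[p - 1] - float(model.recurrence @ y[p - L : p - 1])
            )
            sto = model.forecast_residual(H, rng=rng)
            model.residuals = stale
            pred = det + sto
            if cfg.clamp_output:
                pred = np.clip(pred, *cfg.amplitude_bounds)
        abs_err[i] = np.abs(pred - truth)
        if ssa_err is not None:
            ssa_err[i] = np.abs(det - truth)

    return HorizonErrorTable(
        steps=np.arange(1, H + 1),
        mae=abs_err.mean(axis=0),
        n_origins=int(origins.size),
        abs_errors=abs_err,
        ssa_mae=None if ssa_err is None else ssa_err.mean(axis=0),
    )
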