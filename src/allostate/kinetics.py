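"""Rate-law fitting for substrate-saturation data.

Implements the three phenomenological rate laws used for this enzyme
family (hyperbolic Michaelis-Menten, allosteric sigmoidal/Hill, and
uncompetitive substrate inhibition), weighted nonlinear least squares
with multi-start initialization, and AICc-based model selection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConfigError, FitError, InputError

__all__ = [
    "MODELS",
    "SaturationDataset",
    "KineticFit",
    "FitFailure",
    "rate",
    "fit",
    "efficiency",
    "round_sig",
]

MICHAELIS_MENTEN = "michaelis_menten"
SUBSTRATE_INHIBITION = "substrate_inhibition"
ALLOSTERIC_SIGMOIDAL = "allosteric_sigmoidal"


def _mm(S, Vmax, Km):
    return Vmax * S / (Km + S)


def _sigmoid(S, Vmax, S05, h):
    return Vmax * S**h / (S05**h + S**h)


def _subinh(S, Vmax, Km, Ki):
    return Vmax * S / (Km + S * (1.0 + S / Ki))


MODELS: dict[str, dict] = {
    MICHAELIS_MENTEN: {"func": _mm, "params": ("Vmax", "Km")},
    ALLOSTERIC_SIGMOIDAL: {"func": _sigmoid, "params": ("Vmax", "S05", "h")},
    SUBSTRATE_INHIBITION: {"func": _subinh, "params": ("Vmax", "Km", "Ki")},
}


def rate(model: str, S, params) -> np.ndarray:
    """Evaluate a rate law at substrate concentration(s) S (mM).

    ``params`` is a dict keyed by the model's parameter names or a
    positional sequence in the registry order.
    """
    if model not in MODELS:
        raise InputError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    S = np.asarray(S, dtype=float)
    if (S < 0).any():
        raise InputError("negative substrate concentration")
    names = MODELS[model]["params"]
    if isinstance(params, dict):
        values = [params[n] for n in names]
    else:
        values = list(params)
    if len(values) != len(names):
        raise InputError(f"{model} expects parameters {names}")
    if any(v <= 0 for v in values):
        raise InputError(f"{model} parameters must be positive, got {values}")
    return MODELS[model]["func"](S, *values)


@dataclass
class SaturationDataset:
    """Substrate-saturation measurements: [S] in mM, rates in s^-1 per site.

    If rates are in raw units, supply ``enzyme_conc`` (same unit system)
    so Vmax can be converted to kcat.
    """

    substrate_mM: np.ndarray
    rates: np.ndarray
    substrate: str = "other"
    replicate: np.ndarray | None = None
    enzyme_conc: float | None = None
    no_activity: bool = False

    def __post_init__(self) -> None:
        self.substrate_mM = np.asarray(self.substrate_mM, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.no_activity:
            return
        if self.substrate_mM.shape != self.rates.shape:
            raise InputError("substrate and rate arrays differ in shape")
        if (self.substrate_mM <= 0).any():
            raise InputError("substrate concentrations must be > 0")
        if len(np.unique(self.substrate_mM)) < 5:
            raise InputError(
                "need at least 5 distinct substrate concentrations to fit"
            )

    @classmethod
    def not_detectable(cls, substrate: str = "other") -> "SaturationDataset":
        """Explicit 'not detectable' record; excluded from fitting."""
        return cls(
            substrate_mM=np.array([]), rates=np.array([]),
            substrate=substrate, no_activity=True,
        )

    @classmethod
    def from_csv(cls, path: str | Path, substrate: str = "other") -> "SaturationDataset":
        df = pd.read_csv(path, comment="#")
        if not {"substrate_mM", "rate"} <= set(df.columns):
            raise InputError("CSV needs columns: substrate_mM, rate")
        rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
        enz = float(df["enzyme_uM"].iloc[0]) if "enzyme_uM" in df.columns else None
        return cls(
            substrate_mM=df["substrate_mM"].to_numpy(),
            rates=df["rate"].to_numpy(),
            substrate=substrate,
            replicate=rep,
            enzyme_conc=enz,
        )

    def to_csv(self, path: str | Path) -> Path:
        df = pd.DataFrame({"substrate_mM": self.substrate_mM, "rate": self.rates})
        if self.replicate is not None:
            df["replicate"] = self.replicate
        df.to_csv(path, index=False)
        return Path(path)


@dataclass
class KineticFit:
    """Fitted rate law with uncertainties and goodness-of-fit."""

    model: str
    params: dict[str, float]
    stderr: dict[str, float]
    rss: float
    aicc: float
    n: int
    kcat: float | None
    seed: int
    start_points: list[dict] = field(default_factory=list)
    at_bound: bool = False

    @classmethod
    def from_parameters(
        cls, model: str, kcat: float, half_saturation_mM: float, h: float | None = None
    ) -> "KineticFit":
        """Wrap tabulated (kcat, Km-or-S0.5) values as a fit-like record."""
        if model not in MODELS:
            raise InputError(f"unknown model {model!r}")
        key = "S05" if model == ALLOSTERIC_SIGMOIDAL else "Km"
        params = {"Vmax": kcat, key: half_saturation_mM}
        if model == ALLOSTERIC_SIGMOIDAL:
            params["h"] = h if h is not None else 1.0
        return cls(
            model=model, params=params, stderr={}, rss=float("nan"),
            aicc=float("nan"), n=0, kcat=kcat, seed=0,
        )

    @property
    def half_saturation_mM(self) -> float:
        return self.params["S05" if self.model == ALLOSTERIC_SIGMOIDAL else "Km"]

    def predict(self, S) -> np.ndarray:
        return rate(self.model, S, self.params)

    def to_json(self) -> str:
        payload = {
            "model": self.model,
            "params": self.params,
            "stderr": self.stderr,
            "kcat_per_s": self.kcat,
            "half_saturation_mM": self.half_saturation_mM,
            "efficiency_M_per_s": efficiency(self) if self.kcat is not None else None,
            "rss": self.rss,
            "aicc": self.aicc,
            "n": self.n,
            "seed": self.seed,
            "at_bound": self.at_bound,
        }
        return json.dumps(payload, indent=1)


@dataclass
class FitFailure:
    """Explicit non-convergence record (never silent NaNs)."""

    model: str
    message: str


def _aicc(rss: float, n: int, n_params: int) -> float:
    k = n_params + 1  # + residual variance
    if n - k - 1 <= 0:
        return math.inf
    return n * math.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _start_points(model: str, S: np.ndarray, v: np.ndarray, seed: int, n_starts: int):
    rng = np.random.default_rng(seed)
    vmax0 = 1.1 * v.max()
    half = np.abs(v - vmax0 / 2)
    km0 = float(S[np.argmin(half)])
    base = []
    if model == MICHAELIS_MENTEN:
        base = [{"Vmax": vmax0, "Km": km0}]
    elif model == ALLOSTERIC_SIGMOIDAL:
        base = [{"Vmax": vmax0, "S05": km0, "h": h0} for h0 in (1.5, 2.5)]
    elif model == SUBSTRATE_INHIBITION:
        base = [{"Vmax": vmax0, "Km": km0, "Ki": 10 * km0}]
    starts = list(base)
    while len(starts) < n_starts:
        jittered = {
            k: val * float(rng.lognormal(0.0, 0.5)) for k, val in base[len(starts) % len(base)].items()
        }
        starts.append(jittered)
    return starts[:n_starts]


def _fit_single(
    dataset: SaturationDataset,
    model: str,
    weights: np.ndarray | None,
    n_starts: int,
    seed: int,
) -> KineticFit | FitFailure:
    S, v = dataset.substrate_mM, dataset.rates
    names = MODELS[model]["params"]
    func = MODELS[model]["func"]
    sigma = None if weights is None else 1.0 / np.sqrt(weights)
    lower = np.full(len(names), 1e-12)
    upper = np.full(len(names), np.inf)
    if "h" in names:  # Hill coefficient kept in a sane range
        upper[names.index("h")] = 10.0

    starts = _start_points(model, S, v, seed, n_starts)
    best = None
    stale = 0  # converged starts that failed to improve the best RSS
    for p0 in starts:
        x0 = np.array([max(p0[n], 1e-9) for n in names])
        try:
            popt, pcov = curve_fit(
                func, S, v, p0=x0, sigma=sigma, bounds=(lower, upper), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        resid = func(S, *popt) - v
        if weights is not None:
            resid = resid * np.sqrt(weights)
        rss = float(resid @ resid)
        if best is None or rss < best[0] * (1 - 1e-6):
            best = (rss, popt, pcov)
            stale = 0
        else:
            stale += 1
            if stale >= 2:  # basin repeatedly re-found; further starts add nothing
                break
    if best is None:
        return FitFailure(model=model, message=f"no start converged for {model}")
    rss, popt, pcov = best
    stderr = np.sqrt(np.diag(pcov)) if np.isfinite(pcov).all() else np.full(len(popt), np.nan)
    params = {n: float(p) for n, p in zip(names, popt)}
    at_bound = bool(
        np.any(np.isclose(popt, lower, rtol=0, atol=1e-10))
        or ("h" in names and np.isclose(params["h"], 10.0))
    )
    vmax = params["Vmax"]
    kcat = vmax if dataset.enzyme_conc is None else vmax / dataset.enzyme_conc
    return KineticFit(
        model=model,
        params=params,
        stderr={n: float(s) for n, s in zip(names, stderr)},
        rss=rss,
        aicc=_aicc(rss, len(v), len(names)),
        n=len(v),
        kcat=kcat,
        seed=seed,
        start_points=starts,
        at_bound=at_bound,
    )


def fit(
    dataset: SaturationDataset,
    model: str = "auto",
    weights: str | np.ndarray | None = None,
    n_starts: int = 8,
    seed: int = 0,
    parsimony_delta: float = 2.0,
) -> KineticFit:
    """Fit one rate law, or all three and select by AICc (``model="auto"``).

    Unweighted least squares by default; pass ``weights="1/v2"`` for
    relative (1/v^2) weighting, or an explicit weight array.
    """
    if dataset.no_activity:
        raise InputError("dataset is an explicit no-activity (ND) record; nothing to fit")
    if isinstance(weights, str):
        if weights != "1/v2":
            raise ConfigError(f"unknown weighting scheme {weights!r}")
        weights = 1.0 / np.maximum(dataset.rates, 1e-12) ** 2
    if model == "auto":
        candidates = [
            _fit_single(dataset, m, weights, n_starts, seed) for m in MODELS
        ]
        fits = [c for c in candidates if isinstance(c, KineticFit)]
        if not fits:
            raise FitError(
                "; ".join(c.message for c in candidates if isinstance(c, FitFailure))
            )
        # AICc selection with the usual parsimony tie-break: models within
        # `parsimony_delta` units of the best are considered equivalent and
        # the one with the fewest parameters wins
        best_aicc = min(f.aicc for f in fits)
        eligible = [f for f in fits if f.aicc <= best_aicc + parsimony_delta]
        return min(eligible, key=lambda f: (len(f.params), f.aicc))
    if model not in MODELS:
        raise InputError(f"unknown model {model!r}")
    result = _fit_single(dataset, model, weights, n_starts, seed)
    if isinstance(result, FitFailure):
        raise FitError(result.message)
    return result


def efficiency(fit_result: KineticFit, enzyme_conc: float | None = None) -> float:
    """Catalytic efficiency kcat/Km in M^-1 s^-1.

    The sigmoid half-saturation S0.5 stands in for Km, matching how the
    family literature tabulates "Km or S0.5".
    """
    kcat = fit_result.kcat
    if kcat is None and enzyme_conc is not None:
        kcat = fit_result.params["Vmax"] / enzyme_conc
    if kcat is None:
        raise InputError(
            "no kcat available: supply enzyme_conc to convert Vmax"
        )
    km_mM = fit_result.half_saturation_mM
    return kcat / (km_mM * 1e-3)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
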