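"""Self-scission kinetics: cleaved-fraction calculation, exponential fits,
Hill-type Mg2+ dependence and the two-pKa pH-rate profile.

Models (t in minutes, rates in 1/min):

* mono:  f(t) = 1 - (A exp(-k1 t) + C)
* bi:    f(t) = 1 - (A exp(-k1 t) + B exp(-k2 t) + C)
* Hill:  k_obs(Mg) = k_max / (1 + (K_d / Mg)^n)
* pH:    k_obs(pH) = k_max / (1 + 10^(pH-pKa1) + 10^(pKa2-pH) + 10^(pKa2-pKa1))

The reported k_obs is k1 for mono fits and the faster of the two rates for
biexponential fits.  All fits are unweighted least squares over pooled
replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "KineticTrace",
    "ExponentialFit",
    "HillFit",
    "PHFit",
    "FitError",
    "fraction_cleaved",
    "mono_model",
    "bi_model",
    "hill_model",
    "ph_model",
    "fit_exponential",
    "fit_hill",
    "fit_ph",
    "simulate_trace",
    "simulate_rate_profile",
    "default_timepoints",
]

#: bounds on rate constants (1/min)
K_BOUNDS = (1e-6, 1e3)
#: extra-sum-of-squares F-test level for accepting the biexponential model
F_TEST_ALPHA = 0.01
#: minimum rate separation for accepting the biexponential model
MIN_RATE_RATIO = 3.0


class FitError(RuntimeError):
    """Raised when a nonlinear fit cannot be performed or fails to converge."""


@dataclass
class KineticTrace:
    """Time course of the cleaved fraction for one replicate."""

    times: np.ndarray
    fractions: np.ndarray
    replicate_id: str = "r1"
    condition: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.times.shape != self.fractions.shape:
            raise ValueError("times and fractions must have equal shapes")
        if np.any(self.times < 0):
            raise ValueError("times must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def fraction_cleaved(
    i_trna: float,
    i_substrate: float,
    nc_trna: int = 1,
    nc_substrate: int = 1,
) -> float:
    """Cleaved fraction from band intensities, corrected for cytosine counts.

    f = (I_tRNA/nC_tRNA) / (I_tRNA/nC_tRNA + I_substrate/nC_substrate)
    """
    if i_trna < 0 or i_substrate < 0:
        raise ValueError("band intensities must be >= 0")
    if nc_trna < 1 or nc_substrate < 1:
        raise ValueError("cytosine counts must be >= 1")
    if i_trna == 0 and i_substrate == 0:
        raise ValueError("both band intensities are zero")
    a = i_trna / nc_trna
    b = i_substrate / nc_substrate
    return a / (a + b)


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------

def mono_model(t, a, k1, c):
    return 1.0 - (a * np.exp(-k1 * np.asarray(t, dtype=float)) + c)


def bi_model(t, a, k1, b, k2, c):
    t = np.asarray(t, dtype=float)
    return 1.0 - (a * np.exp(-k1 * t) + b * np.exp(-k2 * t) + c)


def hill_model(mg, k_max, k_d, n):
    return k_max / (1.0 + (k_d / np.asarray(mg, dtype=float)) ** n)


def ph_model(ph, k_max, pka1, pka2):
    ph = np.asarray(ph, dtype=float)
    return k_max / (
        1.0
        + 10.0 ** (ph - pka1)
        + 10.0 ** (pka2 - ph)
        + 10.0 ** (pka2 - pka1)
    )


# ---------------------------------------------------------------------------
# exponential fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExponentialFit:
    model: str  # "mono" or "bi"
    a: float
    b: float
    c: float
    k1: float
    k2: float | None
    k_obs: float
    stderr: Mapping[str, float]
    ssr: float
    n_obs: int
    converged: bool = True


def _pool(traces) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(traces, KineticTrace):
        traces = [traces]
    ts, fs = [], []
    for tr in traces:
        ts.append(tr.times)
        fs.append(tr.fractions)
    t = np.concatenate(ts)
    f = np.concatenate(fs)
    order = np.argsort(t, kind="stable")
    return t[order], f[order]


def _init_rate(t: np.ndarray, f: np.ndarray) -> float:
    """Rate guess from a log-linear regression on the decaying precursor."""
    c = max(0.0, 1.0 - float(np.max(f)) - 0.02)
    y = 1.0 - f - c
    mask = y > 1e-3
    if mask.sum() >= 2:
        slope, _ = np.polyfit(t[mask], np.log(y[mask]), 1)
        if slope < 0:
            return float(np.clip(-slope, *K_BOUNDS))
    t_pos = t[t > 0]
    return 1.0 / float(np.median(t_pos)) if t_pos.size else 1.0


def fit_exponential(
    traces: KineticTrace | Sequence[KineticTrace],
    model: str = "auto",
) -> ExponentialFit:
    """Fit pooled traces to the inverted mono- or biexponential decay.

    ``model`` is "mono", "bi" or "auto".  In auto mode the biexponential is
    accepted only when it wins an extra-sum-of-squares F-test at alpha=0.01
    and the two rates differ at least :data:`MIN_RATE_RATIO`-fold.
    """
    t, f = _pool(traces)
    n_distinct = np.unique(t).size
    if model in ("mono", "auto") and n_distinct < 4:
        raise FitError(f"need >=4 distinct timepoints for a mono fit, got {n_distinct}")
    if model == "bi" and n_distinct < 6:
        raise FitError(f"need >=6 distinct timepoints for a bi fit, got {n_distinct}")

    k0 = _init_rate(t, f)
    c0 = max(0.0, 1.0 - float(np.max(f)))
    a0 = float(np.clip(1.0 - float(np.min(f)) - c0, 0.05, 1.0))

    def _fit_mono():
        p0 = [a0, k0, c0]
        bounds = ([0.0, K_BOUNDS[0], 0.0], [1.05, K_BOUNDS[1], 1.05])
        try:
            popt, pcov = optimize.curve_fit(
                mono_model, t, f, p0=p0, bounds=bounds, maxfev=10_000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except RuntimeError as exc:
            raise FitError(f"mono fit did not converge (p0={p0})") from exc
        ssr = float(np.sum((f - mono_model(t, *popt)) ** 2))
        return popt, pcov, ssr

    def _fit_bi():
        p0 = [a0 / 2, k0 * 3, a0 / 2, k0 / 3, c0]
        bounds = (
            [0.0, K_BOUNDS[0], 0.0, K_BOUNDS[0], 0.0],
            [1.05, K_BOUNDS[1], 1.05, K_BOUNDS[1], 1.05],
        )
        try:
            popt, pcov = optimize.curve_fit(
                bi_model, t, f, p0=p0, bounds=bounds, maxfev=10_000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except RuntimeError as exc:
            raise FitError(f"bi fit did not converge (p0={p0})") from exc
        ssr = float(np.sum((f - bi_model(t, *popt)) ** 2))
        return popt, pcov, ssr

    def _mono_result():
        popt, pcov, ssr = _fit_mono()
        se = np.sqrt(np.clip(np.diag(pcov), 0, None))
        a, k1, c = (float(x) for x in popt)
        return ExponentialFit(
            model="mono", a=a, b=0.0, c=c, k1=k1, k2=None, k_obs=k1,
            stderr={"A": se[0], "k1": se[1], "C": se[2]},
            ssr=ssr, n_obs=t.size,
        )

    def _bi_result():
        popt, pcov, ssr = _fit_bi()
        se = np.sqrt(np.clip(np.diag(pcov), 0, None))
        a, k1, b, k2, c = (float(x) for x in popt)
        return ExponentialFit(
            model="bi", a=a, b=b, c=c, k1=k1, k2=k2, k_obs=max(k1, k2),
            stderr={"A": se[0], "k1": se[1], "B": se[2], "k2": se[3], "C": se[4]},
            ssr=ssr, n_obs=t.size,
        )

    if model == "mono":
        return _mono_result()
    if model == "bi":
        return _bi_result()
    if model != "auto":
        raise ValueError(f"unknown model {model!r}")

    mono = _mono_result()
    if n_distinct < 6 or t.size <= 5:
        return mono
    try:
        bi = _bi_result()
    except FitError:
        return mono
    # extra-sum-of-squares F-test, 2 extra parameters
    df_bi = t.size - 5
    if bi.ssr <= 0 or df_bi <= 0:
        f_stat = np.inf if mono.ssr > bi.ssr else 0.0
        p = 0.0 if f_stat == np.inf else 1.0
    else:
        f_stat = ((mono.ssr - bi.ssr) / 2.0) / (bi.ssr / df_bi)
        p = float(stats.f.sf(f_stat, 2, df_bi)) if f_stat > 0 else 1.0
    ratio = max(bi.k1, bi.k2) / min(bi.k1, bi.k2)
    if p < F_TEST_ALPHA and ratio >= MIN_RATE_RATIO:
        return bi
    return mono


# ---------------------------------------------------------------------------
# Hill and pH fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HillFit:
    k_max: float
    k_d: float
    n: float
    stderr: Mapping[str, float]
    ssr: float


def fit_hill(points: Iterable[tuple[float, float]]) -> HillFit:
    """Least-squares fit of k_obs vs Mg2+ to the Hill equation."""
    pts = sorted(points)
    mg = np.array([p[0] for p in pts], dtype=float)
    k = np.array([p[1] for p in pts], dtype=float)
    if mg.size < 4:
        raise FitError(f"need >=4 Mg2+ concentrations, got {mg.size}")
    if np.any(mg <= 0):
        raise FitError("Mg2+ concentrations must be > 0")
    if np.allclose(k, k[0]):
        raise FitError("degenerate fit: all k_obs equal")
    p0 = [float(np.max(k)), float(np.median(mg)), 1.0]
    bounds = ([1e-9, 1e-9, 0.05], [1e6, 1e6, 10.0])
    try:
        popt, pcov = optimize.curve_fit(
            hill_model, mg, k, p0=p0, bounds=bounds, maxfev=10_000,
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except RuntimeError as exc:
        raise FitError(f"Hill fit did not converge (p0={p0})") from exc
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    ssr = float(np.sum((k - hill_model(mg, *popt)) ** 2))
    return HillFit(
        k_max=float(popt[0]), k_d=float(popt[1]), n=float(popt[2]),
        stderr={"k_max": se[0], "K_d": se[1], "n": se[2]},
        ssr=ssr,
    )


@dataclass(frozen=True)
class PHFit:
    k_max: float
    pka1: float
    pka2: float
    stderr: Mapping[str, float]
    ssr: float
    monotone_warning: bool = False


def fit_ph(points: Iterable[tuple[float, float]]) -> PHFit:
    """Least-squares fit of k_obs vs pH to the two-pKa profile.

    The constraint pKa1 > pKa2 (basic vs acidic limb) is enforced by
    fitting pKa2 and the separation delta = pKa1 - pKa2 >= 0.
    """
    pts = sorted(points)
    ph = np.array([p[0] for p in pts], dtype=float)
    k = np.array([p[1] for p in pts], dtype=float)
    if ph.size < 6:
        raise FitError(f"need >=6 pH points, got {ph.size}")
    monotone = bool(
        np.all(np.diff(k) >= 0) or np.all(np.diff(k) <= 0)
    )
    if monotone:
        warnings.warn(
            "k_obs is monotone in pH (one limb only); pKa estimates will "
            "have wide confidence bounds",
            stacklevel=2,
        )

    peak_ph = float(ph[np.argmax(k)])

    def resid(theta):
        k_max, pka2, delta = theta
        return ph_model(ph, k_max, pka2 + delta, pka2) - k

    p0 = [float(np.max(k)) * 1.05, peak_ph - 1.5, 3.0]
    res = optimize.least_squares(
        resid, p0,
        bounds=([1e-9, 0.0, 0.0], [1e6, 14.0, 14.0]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=10_000,
    )
    if res.status == -1:
        raise FitError(f"pH fit failed (p0={p0})")
    if not res.success:
        warnings.warn("pH fit stopped at the evaluation limit", stacklevel=2)
    k_max, pka2, delta = (float(x) for x in res.x)
    ssr = float(np.sum(res.fun ** 2))
    # standard errors from the Jacobian, propagated to (k_max, pKa1, pKa2)
    try:
        dof = max(ph.size - 3, 1)
        cov = np.linalg.inv(res.jac.T @ res.jac) * (ssr / dof)
        j = np.array([[1, 0, 0], [0, 1, 1], [0, 1, 0]], dtype=float)
        cov_p = j @ cov @ j.T
        se = np.sqrt(np.clip(np.diag(cov_p), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    return PHFit(
        k_max=k_max, pka1=pka2 + delta, pka2=pka2,
        stderr={"k_max": se[0], "pKa1": se[1], "pKa2": se[2]},
        ssr=ssr, monotone_warning=monotone,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_trace(
    model: str,
    params: Mapping[str, float],
    timepoints: Sequence[float],
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int | None = None,
    condition: Mapping[str, float] | None = None,
) -> list[KineticTrace]:
    """Simulate cleaved-fraction traces with i.i.d. Gaussian noise.

    ``model`` is "mono" (params A, k1, C) or "bi" (params A, k1, B, k2, C).
    Noisy fractions are clipped to [0, 1]; the output is deterministic for a
    fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.asarray(timepoints, dtype=float)
    if model == "mono":
        f = mono_model(t, params["A"], params["k1"], params.get("C", 0.0))
    elif model == "bi":
        f = bi_model(
            t, params["A"], params["k1"], params["B"], params["k2"],
            params.get("C", 0.0),
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)
    traces = []
    for i in range(replicates):
        noisy = f + rng.normal(0.0, noise_sd, size=t.shape) if noise_sd else f
        traces.append(
            KineticTrace(
                times=t,
                fractions=np.clip(noisy, 0.0, 1.0),
                replicate_id=f"r{i + 1}",
                condition=dict(condition or {}),
            )
        )
    return traces


def default_timepoints(k: float, n: int = 10) -> np.ndarray:
    """Log-spaced timepoints covering >= 5 half-lives of rate ``k``."""
    t_half = np.log(2.0) / k
    return np.geomspace(t_half / 20.0, 5.0 * t_half, n)


def simulate_rate_profile(
    model: str,
    params: Mapping[str, float],
    xs: Sequence[float],
    rel_noise: float = 0.0,
    seed: int | None = None,
) -> list[tuple[float, float]]:
    """Simulate a k_obs surface over Mg2+ ("hill") or pH ("ph") values."""
    xs = np.asarray(xs, dtype=float)
    if model == "hill":
        k = hill_model(xs, params["k_max"], params["K_d"], params["n"])
    elif model == "ph":
        k = ph_model(xs, params["k_max"], params["pKa1"], params["pKa2"])
    else:
        raise ValueError(f"unknown model {model!r}")
    if rel_noise:
        rng = np.random.default_rng(seed)
        k = np.clip(k * (1.0 + rng.normal(0.0, rel_noise, size=k.shape)), 1e-12, None)
    return list(zip(xs.tolist(), k.tolist()))
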