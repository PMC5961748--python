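"""Polarity-versus-flow statistics.

Four analyses of matched cell/flow pairs:

1. directionality table — counts and ratio of cells polarized against
   the flow (relative angle within 180 +/- 45 degrees by default);
2. polar histogram with Kuiper tests (one-sample against the uniform
   circular distribution, and two-sample between groups);
3. WSS sensor analysis — against-flow fraction binned by WSS magnitude,
   with the threshold where the curve crosses 60%;
4. scalar-product slope — OLS of s = p.t against ||t|| per sign subgroup.

Kuiper's statistic V = D+ + D- is rotation invariant, which is what
makes it appropriate for angular data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "KuiperResult",
    "DirectionalityTable",
    "PolarHistogram",
    "SensorCurve",
    "SlopeFit",
    "against_flow",
    "directionality_table",
    "kuiper_statistic",
    "kuiper_two_sample_statistic",
    "kuiper_fpp",
    "kuiper_one_sample",
    "kuiper_two_sample",
    "rayleigh_test",
    "polar_histogram",
    "sensor_analysis",
    "scalar_product_slopes",
]


# ---------------------------------------------------------------------------
# against-flow window


def against_flow(theta_deg, tolerance_deg: float = 45.0):
    """True where the signed angle lies within 180 +/- tolerance degrees.

    With theta in (-180, 180] this is |theta| >= 180 - tolerance,
    boundary inclusive.
    """
    th = np.abs(np.asarray(theta_deg, dtype=float))
    out = th >= 180.0 - tolerance_deg
    return bool(out) if np.isscalar(theta_deg) else out


@dataclass(frozen=True)
class DirectionalityTable:
    """Per-group counts of cells polarized against the flow."""

    groups: dict[str, dict]  # label -> {n_cells, n_against, ratio (or None)}
    tolerance_deg: float


def directionality_table(
    theta_deg: np.ndarray,
    groups: np.ndarray | None = None,
    tolerance_deg: float = 45.0,
) -> DirectionalityTable:
    """Counts and against-flow ratios per group plus an 'all' row.

    Empty groups report ratio None (undefined), never 0.
    """
    theta = np.asarray(theta_deg, dtype=float)
    ag = against_flow(theta, tolerance_deg)
    labels = np.asarray(groups) if groups is not None else None
    table: dict[str, dict] = {}

    def row(mask):
        n = int(mask.sum())
        na = int(ag[mask].sum())
        return {"n_cells": n, "n_against": na, "ratio": (na / n) if n else None}

    table["all"] = row(np.ones_like(ag, dtype=bool))
    if labels is not None:
        for lab in sorted(set(labels.tolist())):
            table[str(lab)] = row(labels == lab)
    return DirectionalityTable(groups=table, tolerance_deg=tolerance_deg)


# ---------------------------------------------------------------------------
# Kuiper tests


@dataclass(frozen=True)
class KuiperResult:
    statistic: float  # V = D+ + D-
    pvalue: float
    n: int
    m: int | None = None
    method: str = "asymptotic"


def _to_unit(angles_deg: np.ndarray) -> np.ndarray:
    """Map signed degrees in (-180, 180] to [0, 1) on the circle."""
    u = (np.asarray(angles_deg, dtype=float) + 180.0) / 360.0
    return np.mod(u, 1.0)


def kuiper_statistic(u: np.ndarray) -> float:
    """V = D+ + D- of a sample in [0, 1) against the uniform CDF."""
    x = np.sort(np.asarray(u, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - x)
    d_minus = np.max(x - (i - 1) / n)
    return float(d_plus + d_minus)


def kuiper_fpp(V: float, ne: float) -> float:
    """Asymptotic Kuiper false-positive probability with Stephens'
    finite-sample correction; ``ne`` is the (effective) sample size."""
    if V <= 0:
        return 1.0
    lam = (math.sqrt(ne) + 0.155 + 0.24 / math.sqrt(ne)) * V
    if lam < 0.4:
        return 1.0
    p = 0.0
    for j in range(1, 101):
        term = (4.0 * j * j * lam * lam - 1.0) * math.exp(-2.0 * j * j * lam * lam)
        p += term
        if abs(term) < 1e-12:
            break
    return float(min(max(2.0 * p, 0.0), 1.0))


def kuiper_one_sample(
    angles_deg: np.ndarray,
    method: str = "auto",
    n_mc: int = 10_000,
    seed: int | None = 0,
) -> KuiperResult:
    """Kuiper test of angular uniformity.

    Angles (signed degrees) are mapped to [0, 1); the asymptotic p-value
    uses Stephens' correction.  For n < 8 (or ``method='monte_carlo'``)
    the p-value is calibrated against resampled uniform nulls.
    """
    u = _to_unit(angles_deg)
    n = len(u)
    if n == 0:
        raise ValueError("empty sample")
    V = kuiper_statistic(u)
    use_mc = method == "monte_carlo" or (method == "auto" and n < 8)
    if use_mc:
        rng = np.random.default_rng(seed)
        sims = rng.random((n_mc, n))
        sims.sort(axis=1)
        i = np.arange(1, n + 1)
        vs = (i / n - sims).max(axis=1) + (sims - (i - 1) / n).max(axis=1)
        p = float((1 + np.sum(vs >= V - 1e-12)) / (n_mc + 1))
        return KuiperResult(statistic=V, pvalue=p, n=n, method="monte_carlo")
    return KuiperResult(statistic=V, pvalue=kuiper_fpp(V, n), n=n, method="asymptotic")


def kuiper_two_sample_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """V between two samples on [0, 1): max(Fa - Fb) + max(Fb - Fa)
    with right-continuous ECDFs evaluated at the pooled sorted points."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    pooled.sort()
    fa = np.searchsorted(a, pooled, side="right") / len(a)
    fb = np.searchsorted(b, pooled, side="right") / len(b)
    return float(np.max(fa - fb) + np.max(fb - fa))


def kuiper_two_sample(
    a_deg: np.ndarray,
    b_deg: np.ndarray,
    method: str = "asymptotic",
    n_perm: int = 10_000,
    seed: int | None = 0,
) -> KuiperResult:
    """Two-sample Kuiper test between angular samples (signed degrees).

    The asymptotic p-value plugs the effective size nm/(n+m) into the
    one-sample formula; ``method='monte_carlo'`` runs a pooled-relabeling
    permutation test instead.
    """
    ua, ub = _to_unit(a_deg), _to_unit(b_deg)
    n, m = len(ua), len(ub)
    if n == 0 or m == 0:
        raise ValueError("empty sample")
    V = kuiper_two_sample_statistic(ua, ub)
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([ua, ub])
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if kuiper_two_sample_statistic(perm[:n], perm[n:]) >= V - 1e-12:
                count += 1
        p = (1 + count) / (n_perm + 1)
        return KuiperResult(statistic=V, pvalue=float(p), n=n, m=m, method="monte_carlo")
    ne = n * m / (n + m)
    return KuiperResult(statistic=V, pvalue=kuiper_fpp(V, ne), n=n, m=m, method="asymptotic")


def rayleigh_test(angles_deg: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of uniformity (secondary, labeled output).

    Returns (z, p) where z = n * Rbar^2 and p uses the standard
    finite-sample-corrected approximation.
    """
    th = np.deg2rad(np.asarray(angles_deg, dtype=float))
    n = len(th)
    if n == 0:
        raise ValueError("empty sample")
    rbar = float(np.hypot(np.cos(th).sum(), np.sin(th).sum())) / n
    z = n * rbar**2
    p = math.exp(-z) * (1 + (2 * z - z**2) / (4 * n) - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n**2))
    return float(z), float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# polar histogram


@dataclass(frozen=True)
class PolarHistogram:
    bin_edges_deg: np.ndarray  # covering (-180, 180]
    counts: np.ndarray
    group: str = "all"
    folded: bool = False  # True: absolute angle on [0, 180]


def polar_histogram(
    theta_deg: np.ndarray,
    n_bins: int = 24,
    group: str = "all",
    folded: bool = False,
) -> PolarHistogram:
    """Histogram of signed angles over (-180, 180] (default 24 x 15 deg),
    or of |theta| over [0, 180] when ``folded``."""
    th = np.asarray(theta_deg, dtype=float)
    if folded:
        edges = np.linspace(0.0, 180.0, n_bins + 1)
        counts, _ = np.histogram(np.abs(th), bins=edges)
    else:
        edges = np.linspace(-180.0, 180.0, n_bins + 1)
        # numpy's last bin is closed, so +180 lands in the final bin;
        # a -180 input (never produced by relative_angle) aliases to +180
        shifted = np.where(th <= -180.0, th + 360.0, th)
        counts, _ = np.histogram(shifted, bins=edges)
    return PolarHistogram(bin_edges_deg=edges, counts=counts, group=group, folded=folded)


# ---------------------------------------------------------------------------
# WSS sensor analysis


@dataclass(frozen=True)
class SensorCurve:
    """Against-flow fraction as a function of WSS magnitude."""

    bin_edges: np.ndarray  # Pa
    bin_median_tau: np.ndarray  # Pa, x-locations of curve points
    n_per_bin: np.ndarray
    fraction_against: np.ndarray
    threshold_tau: float | None  # Pa, first crossing of threshold_frac
    threshold_frac: float
    threshold_note: str = ""


def sensor_analysis(
    tau: np.ndarray,
    theta_deg: np.ndarray,
    n_bins: int = 8,
    binning: str = "quantile",
    tolerance_deg: float = 45.0,
    threshold_frac: float = 0.60,
    interpolate: bool = True,
) -> SensorCurve:
    """Bin cells by WSS magnitude and find the polarization threshold.

    Default equal-count (quantile) bins; ``binning`` may also be
    'width' (equal width) or 'log' (equal width in log tau).  The
    threshold tau* is where the against-flow fraction first crosses
    ``threshold_frac``, linearly interpolated between consecutive bin
    medians (or the first bin at/above the threshold when
    ``interpolate=False``).  A curve that never crosses leaves tau*
    undefined (None) with a reason in ``threshold_note``.
    """
    tau = np.asarray(tau, dtype=float)
    theta = np.asarray(theta_deg, dtype=float)
    if len(tau) != len(theta):
        raise ValueError("tau and theta must have equal length")
    if len(tau) < n_bins:
        raise ValueError(
            f"only {len(tau)} cells for {n_bins} bins; use fewer bins"
        )
    if binning == "quantile":
        edges = np.quantile(tau, np.linspace(0.0, 1.0, n_bins + 1))
        edges = np.unique(edges)
        if len(edges) < 2:
            edges = np.array([tau.min(), tau.max() + 1e-12])
    elif binning == "width":
        edges = np.linspace(tau.min(), tau.max(), n_bins + 1)
    elif binning == "log":
        lo = max(tau.min(), 1e-12)
        edges = np.geomspace(lo, max(tau.max(), lo * 10), n_bins + 1)
    else:
        raise ValueError(f"unknown binning {binning!r}")
    nb = len(edges) - 1
    idx = np.clip(np.searchsorted(edges, tau, side="right") - 1, 0, nb - 1)
    ag = against_flow(theta, tolerance_deg)
    meds = np.empty(nb)
    ns = np.empty(nb, dtype=int)
    fracs = np.empty(nb)
    for b in range(nb):
        sel = idx == b
        ns[b] = int(sel.sum())
        meds[b] = float(np.median(tau[sel])) if ns[b] else float("nan")
        fracs[b] = float(ag[sel].mean()) if ns[b] else float("nan")
    ok = ns > 0
    meds_ok, fracs_ok = meds[ok], fracs[ok]

    thr: float | None = None
    note = ""
    if len(fracs_ok) and fracs_ok[0] >= threshold_frac:
        thr = float(meds_ok[0])
        note = "curve starts at/above threshold; smallest bin median reported"
    else:
        for i in range(1, len(fracs_ok)):
            if fracs_ok[i] >= threshold_frac:
                if interpolate and fracs_ok[i] > fracs_ok[i - 1]:
                    f0, f1 = fracs_ok[i - 1], fracs_ok[i]
                    x0, x1 = meds_ok[i - 1], meds_ok[i]
                    thr = float(x0 + (threshold_frac - f0) / (f1 - f0) * (x1 - x0))
                else:
                    thr = float(meds_ok[i])
                break
        if thr is None:
            note = (
                f"curve never reaches {threshold_frac:.0%} "
                f"(max fraction {np.nanmax(fracs_ok):.3f})"
            )
    return SensorCurve(
        bin_edges=edges,
        bin_median_tau=meds,
        n_per_bin=ns,
        fraction_against=fracs,
        threshold_tau=thr,
        threshold_frac=threshold_frac,
        threshold_note=note,
    )


# ---------------------------------------------------------------------------
# scalar-product slope


@dataclass(frozen=True)
class SlopeFit:
    subgroup: str  # "positive" | "negative"
    n: int
    slope: float | None = None  # um (estimate of ||p|| cos(theta))
    intercept: float | None = None
    pearson_r: float | None = None
    note: str = ""


def scalar_product_slopes(s: np.ndarray, t_mag: np.ndarray) -> list[SlopeFit]:
    """OLS of the scalar product s = p.t against ||t|| per sign subgroup.

    s = 0 pairs are excluded from both subgroups (reported via the
    counts: n_pos + n_neg + n_zero = total).  Fits need n >= 3; smaller
    subgroups are reported without a fit.  A larger negative slope means
    a stronger against-flow polarization response per unit WSS.
    """
    s = np.asarray(s, dtype=float)
    t = np.asarray(t_mag, dtype=float)
    fits = []
    for name, mask in (("positive", s > 0), ("negative", s < 0)):
        n = int(mask.sum())
        if n < 3:
            fits.append(SlopeFit(subgroup=name, n=n, note="fewer than 3 cells; fit skipped"))
            continue
        x, y = t[mask], s[mask]
        if np.ptp(x) == 0.0:
            fits.append(SlopeFit(subgroup=name, n=n, note="degenerate: constant ||t||"))
            continue
        res = sps.linregress(x, y)
        fits.append(
            SlopeFit(
                subgroup=name,
                n=n,
                slope=float(res.slope),
                intercept=float(res.intercept),
                pearson_r=float(res.rvalue),
            )
        )
    return fits
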