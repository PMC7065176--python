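"""Windowed linkage-disequilibrium decay: pairwise r^2 in overlapping genomic
windows, Hill & Weir (1988) expectation-curve fitting, and half-maximal-r^2
distances.

The decay model is ``E[r^2](C, n)`` with ``C = rho * d`` a population-scaled
recombination distance (``rho`` per bp, ``d`` in bp) and ``n`` the chromosome
sample size:

    E[r^2] = (10 + C) / ((2 + C)(11 + C))
             * [1 + (3 + C)(12 + 12C + C^2) / (n (2 + C)(11 + C))]
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize

from .genio import GenotypeMatrix

__all__ = [
    "GenomicWindow",
    "LDWindowFit",
    "make_windows",
    "pairwise_r2",
    "hill_weir_expectation",
    "fit_hill_weir",
    "half_decay_distance",
    "summarize_ld",
    "ld_decay_table",
]


@dataclass(frozen=True)
class GenomicWindow:
    """Half-open window [start, end) on a chromosome, 0-based bp."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")


@dataclass
class LDWindowFit:
    """Result of fitting the decay curve within one window.

    ``rho_hat`` is the per-bp rate such that ``C = rho_hat * distance``;
    ``half_decay_bp`` is None when the asymptote 1/n exceeds half the
    zero-distance curve value, and when the fit failed.
    """

    window: GenomicWindow | None
    rho_hat: float | None
    n: int
    n_pairs: int
    half_decay_bp: float | None
    residual_norm: float | None
    status: str = "ok"  # ok | failed | too_few_pairs
    extras: dict = field(default_factory=dict)


def make_windows(chrom_lengths: dict[str, int], window_bp: int = 30_000,
                 overlap_bp: int = 10_000) -> list[GenomicWindow]:
    """Tile chromosomes with fixed-size windows advancing by
    ``window_bp - overlap_bp``; the last window is truncated at the chromosome
    end so every position is covered."""
    if not 0 <= overlap_bp < window_bp:
        raise ValueError("need 0 <= overlap < window")
    step = window_bp - overlap_bp
    out: list[GenomicWindow] = []
    for chrom in sorted(chrom_lengths):
        length = int(chrom_lengths[chrom])
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        start = 0
        while True:
            end = min(start + window_bp, length)
            out.append(GenomicWindow(chrom, start, end))
            if end >= length:
                break
            start += step
    return out


def pairwise_r2(gm: GenotypeMatrix, window: GenomicWindow | None = None,
                min_complete: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Composite (dosage) r^2 for all SNP pairs in a window.

    r^2 is the squared Pearson correlation of dosage vectors over
    pairwise-complete samples; pairs with fewer than ``min_complete``
    complete samples or zero variance at either locus are skipped. Returns
    (distances bp, r^2) arrays, possibly empty.
    """
    loci = gm.loci
    if window is not None:
        mask = (
            (loci["chrom"] == window.chrom)
            & (loci["pos"] - 1 >= window.start)
            & (loci["pos"] - 1 < window.end)
        ).to_numpy()
        G = gm.dosages[:, mask]
        pos = loci.loc[mask, "pos"].to_numpy()
    else:
        if loci["chrom"].nunique() > 1:
            raise ValueError("pass a window when the matrix spans chromosomes")
        G = gm.dosages
        pos = loci["pos"].to_numpy()
    m = G.shape[1]
    if m < 2:
        return np.array([]), np.array([])
    corr = pd.DataFrame(G).corr(min_periods=min_complete).to_numpy()
    iu = np.triu_indices(m, k=1)
    r2 = corr[iu] ** 2
    dist = np.abs(pos[iu[1]] - pos[iu[0]]).astype(float)
    ok = np.isfinite(r2)
    return dist[ok], r2[ok]


def hill_weir_expectation(C, n):
    """Expected r^2 at scaled recombination distance C for n sampled
    chromosomes. Vectorized over C."""
    C = np.asarray(C, dtype=float)
    if (C < 0).any():
        raise ValueError("C must be >= 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    lead = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    corr = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (n * (2.0 + C) * (11.0 + C))
    out = lead * corr
    return float(out) if out.ndim == 0 else out


def _objective(log_rho: float, dist: np.ndarray, r2: np.ndarray, n: int) -> float:
    pred = hill_weir_expectation(np.exp(log_rho) * dist, n)
    return float(np.sum((pred - r2) ** 2))


def fit_hill_weir(dist: np.ndarray, r2: np.ndarray, n: int,
                  min_pairs: int = 50,
                  starts: tuple[float, ...] = (1e-5, 1e-3, 1e-1),
                  window: GenomicWindow | None = None) -> LDWindowFit:
    """Least-squares fit of the per-bp rate rho in ``E[r^2](rho*d, n)``.

    Positivity is enforced by optimizing log rho; each start in ``starts`` is
    polished with L-BFGS-B (objective tolerance 1e-10) and the best kept. A
    window with fewer than ``min_pairs`` pairs, or fewer than 2 distinct
    distances, is returned with status ``too_few_pairs``; non-convergence of
    every start flags ``failed``.
    """
    dist = np.asarray(dist, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    n_pairs = len(dist)
    if n_pairs < min_pairs or len(np.unique(dist)) < 2:
        return LDWindowFit(window, None, n, n_pairs, None, None, "too_few_pairs")
    best = None
    for rho0 in starts:
        res = minimize(
            _objective, x0=np.array([np.log(rho0)]), args=(dist, r2, n),
            method="L-BFGS-B", options={"ftol": 1e-10, "gtol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        return LDWindowFit(window, None, n, n_pairs, None, None, "failed")
    rho_hat = float(np.exp(best.x[0]))
    fit = LDWindowFit(window, rho_hat, n, n_pairs, None, float(np.sqrt(best.fun)))
    fit.half_decay_bp = half_decay_distance(fit)
    return fit


def half_decay_distance(fit: LDWindowFit, xtol: float = 1e-3) -> float | None:
    """Smallest distance d where the fitted curve reaches half its d=0 value.

    Undefined (None) when the large-distance asymptote 1/n already exceeds
    half the zero-distance value. Solved by doubling-bracket plus Brent
    bisection; default tolerance far inside the 0.5 bp contract.
    """
    if fit.rho_hat is None:
        return None
    rho, n = fit.rho_hat, fit.n
    target = hill_weir_expectation(0.0, n) / 2.0
    if 1.0 / n >= target:
        return None

    def f(d):
        return hill_weir_expectation(rho * d, n) - target

    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e15:
            return None
    lo = 0.0 if hi == 1.0 else hi / 2.0
    return float(brentq(f, lo, hi, xtol=xtol))


def summarize_ld(fits: list[LDWindowFit]) -> dict:
    """Median and IQR of half-decay distances over windows with a defined
    value, plus counts of failed / underfilled / undefined windows."""
    values = np.array([f.half_decay_bp for f in fits
                       if f.status == "ok" and f.half_decay_bp is not None])
    n_failed = sum(f.status == "failed" for f in fits)
    n_skipped = sum(f.status == "too_few_pairs" for f in fits)
    n_undefined = sum(f.status == "ok" and f.half_decay_bp is None for f in fits)
    if len(values) == 0:
        raise ValueError("no window has a defined half-decay distance")
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    return {
        "median_bp": float(q50),
        "iqr_low_bp": float(q25),
        "iqr_high_bp": float(q75),
        "n_windows": len(fits),
        "n_defined": len(values),
        "n_failed": n_failed,
        "n_too_few_pairs": n_skipped,
        "n_undefined": n_undefined,
    }


def ld_decay_table(gm: GenotypeMatrix, window_bp: int = 30_000,
                   overlap_bp: int = 10_000, min_pairs: int = 50,
                   n_override: int | None = None) -> tuple[pd.DataFrame, list[LDWindowFit]]:
    """Run the full windowed pipeline on a genotype matrix.

    The chromosome sample size n defaults to 2 x (diploids with any data in
    the window); ``n_override`` replaces it globally. Returns a per-window
    table and the fit objects.
    """
    lengths = gm.loci.groupby("chrom")["pos"].max().to_dict()
    fits: list[LDWindowFit] = []
    rows = []
    for win in make_windows(lengths, window_bp, overlap_bp):
        mask = (
            (gm.loci["chrom"] == win.chrom)
            & (gm.loci["pos"] - 1 >= win.start)
            & (gm.loci["pos"] - 1 < win.end)
        ).to_numpy()
        sub = gm.dosages[:, mask]
        if n_override is not None:
            n = n_override
        else:
            n = 2 * int(np.sum((~np.isnan(sub)).any(axis=1)))
        dist, r2 = pairwise_r2(gm, win)
        if n < 2:
            fit = LDWindowFit(win, None, n, len(dist), None, None, "too_few_pairs")
        else:
            fit = fit_hill_weir(dist, r2, n, min_pairs=min_pairs, window=win)
        fits.append(fit)
        rows.append({
            "chrom": win.chrom, "start": win.start, "end": win.end,
            "n_pairs": fit.n_pairs, "rho_hat": fit.rho_hat, "n": fit.n,
            "half_decay_bp": fit.half_decay_bp, "status": fit.status,
        })
    return pd.DataFrame(rows), fits
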