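"""Distance-distribution statistics for telomere-gene proximity assays.

Three questions are answered here.  (1) Do two experimental conditions
(e.g. population doublings of a fibroblast line) differ in their
gene-subtelomere distance distributions?  — two-sample Kolmogorov-Smirnov
test on the corrected pair distances.  (2) What fraction of pairs is
"interacting"?  — the unimodal distance histogram (a dominant
short-distance lobe plus a long tail) is split by Rosin's corner rule, or
at a fixed cutoff, into interacting main lobe vs non-interacting tail.
(3) How many cells must be imaged to distinguish two conditions reliably?
— for increasing subpopulation sizes, bootstrap resamples of cells are
drawn from both conditions and KS-tested; the minimum cell number is the
smallest size at which at least 98% of resample pairs differ
significantly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import distributions

DEFAULT_BIN_WIDTH_UM = 0.1
DEFAULT_N_BOOT = 500
DEFAULT_BOOT_ALPHA = 1e-3
DEFAULT_BOOT_CRITERION = 0.98


@dataclass
class DistanceDataset:
    """Corrected pair distances for one condition.

    Each nucleus (cell) contributes up to two distances (the two alleles);
    ``nucleus_ids`` records the cell of origin so resampling can operate
    on cells rather than on pooled distances.
    """

    label: str
    distances_um: np.ndarray
    nucleus_ids: np.ndarray

    def __post_init__(self) -> None:
        self.distances_um = np.asarray(self.distances_um, dtype=float).ravel()
        self.nucleus_ids = np.asarray(self.nucleus_ids).ravel()
        if self.distances_um.size != self.nucleus_ids.size:
            raise ValueError("distances and nucleus ids must align")
        if np.any(self.distances_um < 0):
            raise ValueError("distances must be non-negative")

    @classmethod
    def from_distances(cls, label: str, distances_um) -> "DistanceDataset":
        d = np.asarray(distances_um, dtype=float).ravel()
        return cls(label, d, np.arange(d.size))

    @property
    def n_cells(self) -> int:
        return int(np.unique(self.nucleus_ids).size)

    def cell_groups(self) -> List[np.ndarray]:
        """Per-cell distance arrays, in first-appearance order."""
        ids, inverse = np.unique(self.nucleus_ids, return_inverse=True)
        return [self.distances_um[inverse == k] for k in range(ids.size)]


@dataclass
class PopulationSplit:
    threshold_um: float
    interacting_fraction: float
    noninteracting_fraction: float


@dataclass
class BootstrapResult:
    sizes: np.ndarray
    fraction_significant: np.ndarray
    min_cells: Optional[int]  # None = criterion not reached on the grid
    n_boot: int
    alpha: float
    criterion: float
    seed: int


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS statistic D = sup |ECDF_a - ECDF_b|."""
    a = np.sort(a)
    b = np.sort(b)
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


def ks_compare(a, b) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Accepts :class:`DistanceDataset` or plain arrays; returns (D, p) with
    the asymptotic Kolmogorov p-value
    ``p = Q_KS(sqrt(m n / (m + n)) * D)``.
    """
    xa = a.distances_um if isinstance(a, DistanceDataset) else \
        np.asarray(a, dtype=float).ravel()
    xb = b.distances_um if isinstance(b, DistanceDataset) else \
        np.asarray(b, dtype=float).ravel()
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both samples must be nonempty")
    d = _ks_statistic(xa, xb)
    en = np.sqrt(xa.size * xb.size / (xa.size + xb.size))
    p = float(np.clip(distributions.kstwobign.sf(en * d), 0.0, 1.0))
    return d, p


def split_at(distances_um, threshold_um: float) -> PopulationSplit:
    """Fixed-cutoff split; a distance exactly at the threshold counts as
    interacting."""
    if threshold_um <= 0:
        raise ValueError("threshold must be positive")
    d = np.asarray(distances_um, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("no distances")
    frac = float(np.mean(d <= threshold_um))
    return PopulationSplit(threshold_um, frac, 1.0 - frac)


def rosin_threshold(distances_um,
                    bin_width_um: float = DEFAULT_BIN_WIDTH_UM
                    ) -> PopulationSplit:
    """Rosin's unimodal threshold on the distance histogram.

    A chord is drawn from the histogram peak to the last nonempty bin; the
    threshold is the centre of the bin maximising the perpendicular
    distance to that chord.  Requires a dominant mode with a right tail;
    degenerate histograms (all mass in one bin, or peak in the last bin)
    raise ``ValueError``.
    """
    d = np.asarray(distances_um, dtype=float).ravel()
    if d.size < 2:
        raise ValueError("too few distances")
    if bin_width_um <= 0:
        raise ValueError("bin width must be positive")
    n_bins = int(np.ceil((d.max() + 1e-9) / bin_width_um))
    n_bins = max(n_bins, 1)
    counts, edges = np.histogram(d, bins=n_bins,
                                 range=(0.0, n_bins * bin_width_um))
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(counts))
    nonempty = np.nonzero(counts)[0]
    last = int(nonempty[-1])
    if last <= peak:
        raise ValueError("degenerate histogram: no tail beyond the peak")
    # perpendicular distance of (x_k, h_k) to the peak->tail chord
    x0, y0 = centers[peak], float(counts[peak])
    x1, y1 = centers[last], float(counts[last])
    norm = np.hypot(x1 - x0, y1 - y0)
    ks = np.arange(peak, last + 1)
    dist = np.abs((y1 - y0) * centers[ks] - (x1 - x0) * counts[ks]
                  + x1 * y0 - y1 * x0) / norm
    thr = float(centers[ks[int(np.argmax(dist))]])
    return split_at(d, thr)


def tail_quantile_flag(reference, test, q: float = 0.99) -> float:
    """Fraction of ``test`` distances strictly beyond the empirical
    q-quantile of ``reference``."""
    ref = reference.distances_um if isinstance(reference, DistanceDataset) \
        else np.asarray(reference, dtype=float).ravel()
    tst = test.distances_um if isinstance(test, DistanceDataset) \
        else np.asarray(test, dtype=float).ravel()
    if ref.size == 0:
        raise ValueError("reference must be nonempty")
    cut = float(np.quantile(ref, q))
    return float(np.mean(tst > cut))


def bootstrap_min_cells(a: DistanceDataset, b: DistanceDataset,
                        sizes: Sequence[int],
                        n_boot: int = DEFAULT_N_BOOT,
                        alpha: float = DEFAULT_BOOT_ALPHA,
                        criterion: float = DEFAULT_BOOT_CRITERION,
                        seed: int = 0) -> BootstrapResult:
    """Minimum cell number for a reliable condition distinction.

    For each subpopulation size s, draw ``n_boot`` resamples (cells, with
    replacement) from each condition, KS-test every resample pair at level
    ``alpha``, and record the fraction of significant pairs.  The minimum
    cell number is the smallest s whose fraction reaches ``criterion``.
    """
    sizes = np.asarray(sorted(int(s) for s in sizes))
    if sizes.size == 0 or sizes[0] <= 0:
        raise ValueError("sizes must be positive")
    if a.distances_um.size == 0 or b.distances_um.size == 0:
        raise ValueError("both datasets must be nonempty")
    rng = np.random.default_rng(seed)
    cells_a = a.cell_groups()
    cells_b = b.cell_groups()

    fractions = np.empty(sizes.size)
    for si, s in enumerate(sizes):
        n_sig = 0
        for _ in range(n_boot):
            xa = np.concatenate(
                [cells_a[k] for k in rng.integers(0, len(cells_a), size=s)])
            xb = np.concatenate(
                [cells_b[k] for k in rng.integers(0, len(cells_b), size=s)])
            _, p = ks_compare(xa, xb)
            n_sig += p < alpha
        fractions[si] = n_sig / n_boot

    reached = np.nonzero(fractions >= criterion)[0]
    min_cells = int(sizes[reached[0]]) if reached.size else None
    return BootstrapResult(sizes, fractions, min_cells, n_boot, alpha,
                           criterion, seed)


def summarize(dataset: DistanceDataset,
              fixed_threshold_um: Optional[float] = None,
              bin_width_um: float = DEFAULT_BIN_WIDTH_UM) -> dict:
    """Condition-level summary: n, quantiles, and interaction splits."""
    d = dataset.distances_um
    out = {
        "label": dataset.label,
        "n_distances": int(d.size),
        "n_cells": dataset.n_cells,
        "quantiles_um": {str(q): float(np.quantile(d, q))
                         for q in (0.25, 0.5, 0.75, 0.99)},
    }
    try:
        rosin = rosin_threshold(d, bin_width_um)
        out["rosin"] = {
            "threshold_um": rosin.threshold_um,
            "interacting_fraction": rosin.interacting_fraction,
        }
    except ValueError as exc:
        out["rosin"] = {"error": str(exc)}
    if fixed_threshold_um is not None:
        sp = split_at(d, fixed_threshold_um)
        out["fixed_split"] = {
            "threshold_um": sp.threshold_um,
            "interacting_fraction": sp.interacting_fraction,
        }
    return out
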