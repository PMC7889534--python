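"""Cross-channel spot pairing and chromatic-shift correction.

Within each nucleus, every FITC/TRITC spot pair (i, j) with a 3D distance
below 5 μm enters a bipartite candidate graph, scored by

    S_ij = d_ij / sqrt(I_i * I_j)

so bright, close pairs score lowest.  The two mutually exclusive pairs
with the smallest score sum are selected (the two alleles), and the
nucleus is accepted only if those scores are 50% smaller than the best
remaining candidate score — an ambiguity guard that eliminates nuclei
with poor hybridisation rather than risking mispairing.

Residual chromatic aberration between the channels is removed at the
cohort level: the mean FITC-to-TRITC displacement vector over all accepted
pairs of one experiment is subtracted from every individual displacement,
leaving a corrected displacement distribution with mean exactly [0, 0, 0].
This assumes most displacements are short and isotropic, i.e. most pairs
interact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .detect import SpotDetection, spot_intensity

DEFAULT_RADIUS_UM = 5.0
DEFAULT_ACCEPT_RATIO = 0.5


@dataclass
class CandidatePair:
    i: int  # FITC spot index
    j: int  # TRITC spot index
    displacement_um: np.ndarray  # TRITC - FITC, (x, y, z)
    distance_um: float
    intensity_i: float
    intensity_j: float
    score: float

    @property
    def key(self) -> Tuple[int, int]:
        return (self.i, self.j)


@dataclass
class NucleusPairing:
    nucleus_id: int
    pairs: Tuple[CandidatePair, CandidatePair] | None
    best_other_score: Optional[float]
    accepted: bool
    reason: Optional[str] = None  # set when not accepted


@dataclass
class ShiftCorrection:
    """Mean FITC->TRITC displacement over one experiment and the corrected
    per-pair displacements/distances."""

    mean_displacement_um: np.ndarray
    corrected_displacements_um: np.ndarray  # (n, 3)
    corrected_distances_um: np.ndarray  # (n,)


def pair_score(distance_um: float, intensity_i: float,
               intensity_j: float) -> float:
    """S_ij = d_ij / sqrt(I_i * I_j)."""
    if intensity_i <= 0 or intensity_j <= 0:
        raise ValueError("intensities must be positive")
    return distance_um / np.sqrt(intensity_i * intensity_j)


def build_candidate_graph(fitc: Sequence[SpotDetection],
                          tritc: Sequence[SpotDetection],
                          radius_um: float = DEFAULT_RADIUS_UM
                          ) -> List[CandidatePair]:
    """All cross-channel pairs closer than ``radius_um``, scored."""
    graph: List[CandidatePair] = []
    for i, f in enumerate(fitc):
        for j, t in enumerate(tritc):
            disp = np.asarray(t.pos_um, float) - np.asarray(f.pos_um, float)
            d = float(np.linalg.norm(disp))
            if d < radius_um:
                graph.append(CandidatePair(
                    i=i, j=j, displacement_um=disp, distance_um=d,
                    intensity_i=spot_intensity(f),
                    intensity_j=spot_intensity(t),
                    score=pair_score(d, spot_intensity(f),
                                     spot_intensity(t)),
                ))
    return graph


def solve_top2_assignment(graph: Sequence[CandidatePair]
                          ) -> Optional[Tuple[CandidatePair, CandidatePair]]:
    """The two vertex-disjoint candidate pairs with the smallest score sum.

    Returns None when no two disjoint pairs exist (e.g. fewer than two
    spots in a channel).  Ties are broken lexicographically on the sorted
    ((i, j), (i, j)) index couple, so the result is reproducible.

    Edges are scanned in ascending score order with a lower-bound cutoff,
    which keeps the search effectively linear for the graphs this pipeline
    produces (a handful of spots per channel).
    """
    edges = sorted(graph, key=lambda e: (e.score, e.i, e.j))
    if len(edges) < 2:
        return None
    best_sum = np.inf
    best: Optional[Tuple[CandidatePair, CandidatePair]] = None
    best_key = None
    s_min = edges[0].score
    for a_idx, ea in enumerate(edges):
        if ea.score + s_min > best_sum:
            break  # no later edge can improve the optimum
        for eb in edges[a_idx + 1:]:
            if ea.score + eb.score > best_sum:
                break
            if ea.i == eb.i or ea.j == eb.j:
                continue
            s = ea.score + eb.score
            key = tuple(sorted([ea.key, eb.key]))
            if s < best_sum or (s == best_sum
                                and (best_key is None or key < best_key)):
                best_sum = s
                best = (ea, eb)
                best_key = key
    if best is None:
        return None
    # canonical order: lexicographic by (i, j)
    pa, pb = sorted(best, key=lambda e: e.key)
    return (pa, pb)


def acceptance_test(pair_a: CandidatePair, pair_b: CandidatePair,
                    graph: Sequence[CandidatePair],
                    ratio: float = DEFAULT_ACCEPT_RATIO) -> bool:
    """The "50% smaller than the following score" rule.

    Accepted iff max(S_A, S_B) <= ratio * S_next, where S_next is the
    smallest score among all candidates other than the selected two.
    Vacuously accepted when no other candidate exists.
    """
    selected = {pair_a.key, pair_b.key}
    others = [e.score for e in graph if e.key not in selected]
    if not others:
        return True
    s_next = min(others)
    return max(pair_a.score, pair_b.score) <= ratio * s_next


def pair_nucleus(fitc: Sequence[SpotDetection],
                 tritc: Sequence[SpotDetection],
                 nucleus_id: int,
                 radius_um: float = DEFAULT_RADIUS_UM,
                 ratio: float = DEFAULT_ACCEPT_RATIO) -> NucleusPairing:
    """Full per-nucleus pairing: graph, top-2 assignment, acceptance."""
    graph = build_candidate_graph(fitc, tritc, radius_um)
    top2 = solve_top2_assignment(graph)
    if top2 is None:
        return NucleusPairing(nucleus_id, None, None, False,
                              reason="infeasible")
    selected = {top2[0].key, top2[1].key}
    others = [e.score for e in graph if e.key not in selected]
    best_other = min(others) if others else None
    ok = acceptance_test(top2[0], top2[1], graph, ratio)
    return NucleusPairing(nucleus_id, top2, best_other, ok,
                          reason=None if ok else "score_ratio")


def correct_chromatic_shift(displacements_um: np.ndarray) -> ShiftCorrection:
    """Subtract the cohort-mean displacement (one experiment at a time).

    ``displacements_um`` is an (n, 3) array of raw FITC->TRITC displacement
    vectors from accepted pairings.  The corrected set has component-wise
    mean exactly (0, 0, 0).
    """
    disp = np.atleast_2d(np.asarray(displacements_um, dtype=float))
    if disp.size == 0:
        raise ValueError("no displacements to correct")
    if disp.shape[1] != 3:
        raise ValueError("displacements must be (n, 3)")
    mean = disp.mean(axis=0)
    corrected = disp - mean
    return ShiftCorrection(
        mean_displacement_um=mean,
        corrected_displacements_um=corrected,
        corrected_distances_um=np.linalg.norm(corrected, axis=1),
    )
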