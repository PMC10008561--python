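"""Per-frame metrics, three-state classification, occupancy and statistics.

The intracellular interface of the receptor is classified into three states
from two geometric observables: frames are *occluded* when the bottom of TM7
approaches TM2 (T94(2.39)–D334(8.47) contact below a distance cutoff),
otherwise *alternative* when TM7 has rotated clockwise past a signed-angle
cutoff, and *canonical* otherwise.  The precedence is fixed: the contact rule
is tested first, and all thresholds are strict ``<``.

Occupancies are computed per replicate (one independent simulation each) and
pooled; condition comparisons use replicate-level fractions with an exact rank
test or a seeded Monte-Carlo permutation test.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import geometry
from .traj import AlignmentSpec, Frame, ResidueMap, Trajectory, superpose


class StateLabel(str, Enum):
    OCCLUDED = "occluded"
    ALTERNATIVE = "alternative"
    CANONICAL = "canonical"


STATE_ORDER = (StateLabel.OCCLUDED, StateLabel.ALTERNATIVE, StateLabel.CANONICAL)

#: FrameMetrics column names, one row per frame.
METRIC_COLUMNS = (
    "frame_index",
    "t94_d334_distance",
    "tm7_rotation",
    "q115_dihedral",
    "k227_e297_distance",
    "w287_z_displacement",
)


@dataclass
class MetricConfig:
    """Thresholds for classification and derived side-chain summaries.

    occluded_distance_cutoff : Å, TM2–TM7 contact rule (strict ``<``)
    tm7_rotation_cutoff      : degrees, signed TM7 rotation rule (strict ``<``)
    salt_bridge_cutoff       : Å, K227–E297 salt bridge formed when below
    w287_down_cutoff         : Å, W287 counted "downward" when z-displacement ≤ cutoff
    q115_window              : degrees; Q115 counted "toward TM1" when its
                               dihedral is more than this far (on the circle)
                               from the crystallographic value
    """

    occluded_distance_cutoff: float = 3.5
    tm7_rotation_cutoff: float = -20.0
    salt_bridge_cutoff: float = 4.0
    w287_down_cutoff: float = -0.5
    q115_window: float = 60.0

    def __post_init__(self) -> None:
        if self.occluded_distance_cutoff <= 0 or self.salt_bridge_cutoff <= 0:
            raise ValueError("distance cutoffs must be positive")
        if not np.isfinite(self.tm7_rotation_cutoff):
            raise ValueError("tm7 rotation cutoff must be finite")


def compute_frame_metrics(
    traj: Trajectory,
    rmap: ResidueMap,
    spec: AlignmentSpec,
    clockwise_positive: bool = False,
) -> pd.DataFrame:
    """Superpose each frame onto the reference and evaluate all five observables.

    Returns a table with one row per frame (columns in :data:`METRIC_COLUMNS`).
    """
    ref = spec.reference
    w287_sel = [("6.48", a) for a in geometry.GROUP_ATOMS["TRP_ring"]]
    rows = []
    for frame in traj:
        aligned, _ = superpose(frame, spec)
        d_t94 = geometry.min_pair_distance(
            np.array([rmap.resolve("2.39", "OG1", aligned)]),
            np.array([rmap.resolve("8.47", a, aligned) for a in ("OD1", "OD2")]),
        )
        rot = geometry.xy_rotation_angle(
            aligned, ref, rmap, clockwise_positive=clockwise_positive
        )
        dih = geometry.dihedral(
            *(rmap.resolve("2.60", a, aligned) for a in geometry.GROUP_ATOMS["GLN_dihedral"])
        )
        d_salt = geometry.min_pair_distance(
            np.array([rmap.resolve("5.39", "NZ", aligned)]),
            np.array([rmap.resolve("6.58", a, aligned) for a in ("OE1", "OE2")]),
        )
        dz = geometry.z_displacement(aligned, ref, rmap, w287_sel)
        rows.append((frame.index, d_t94, rot, dih, d_salt, dz))
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def classify_frame(metrics_row: Mapping[str, float], cfg: MetricConfig | None = None) -> StateLabel:
    """Three-state label for one frame's metrics.

    Precedence: occluded if the T94–D334 distance is below the contact cutoff
    (regardless of rotation), else alternative if the TM7 rotation is below the
    rotation cutoff, else canonical.  Both tests are strict ``<``.
    """
    cfg = cfg or MetricConfig()
    if metrics_row["t94_d334_distance"] < cfg.occluded_distance_cutoff:
        return StateLabel.OCCLUDED
    if metrics_row["tm7_rotation"] < cfg.tm7_rotation_cutoff:
        return StateLabel.ALTERNATIVE
    return StateLabel.CANONICAL


def classify_frames(metrics: pd.DataFrame, cfg: MetricConfig | None = None) -> list[StateLabel]:
    cfg = cfg or MetricConfig()
    return [classify_frame(row, cfg) for _, row in metrics.iterrows()]


@dataclass
class StateOccupancy:
    """Per-replicate and pooled state fractions for one condition.

    ``pooled`` is frame-weighted (total frames in each state / total frames);
    ``replicate_mean`` is the unweighted mean of per-replicate fractions.
    """

    condition: str
    per_replicate: pd.DataFrame  # index replicate_id, columns state names
    n_frames: pd.Series  # frames per replicate
    pooled: dict[str, float] = field(init=False)
    replicate_mean: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        w = self.n_frames.reindex(self.per_replicate.index)
        totals = self.per_replicate.mul(w, axis=0).sum()
        self.pooled = (totals / w.sum()).to_dict()
        self.replicate_mean = self.per_replicate.mean().to_dict()

    def fractions(self, state: StateLabel | str) -> np.ndarray:
        """Per-replicate fractions of one state, for condition comparisons."""
        return self.per_replicate[str(StateLabel(state).value)].to_numpy()


def occupancy(
    labels_by_replicate: Mapping[str, Sequence[StateLabel]], condition: str = ""
) -> StateOccupancy:
    """State fractions per replicate plus frame-weighted pooled fractions."""
    if not labels_by_replicate:
        raise ValueError("at least one replicate required")
    rows, counts = {}, {}
    for rep, labels in labels_by_replicate.items():
        labels = list(labels)
        if not labels:
            raise ValueError(f"replicate {rep!r} has no frames")
        n = len(labels)
        rows[rep] = {s.value: sum(1 for l in labels if l == s) / n for s in STATE_ORDER}
        counts[rep] = n
    per_rep = pd.DataFrame.from_dict(rows, orient="index")[[s.value for s in STATE_ORDER]]
    return StateOccupancy(condition, per_rep, pd.Series(counts, name="n_frames"))


_PREDICATE_OPS: dict[str, Callable[[np.ndarray, float], np.ndarray]] = {
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
}


def fraction_satisfying(
    series_by_replicate: Mapping[str, Sequence[float]],
    predicate: tuple[str, float] | Callable[[np.ndarray], np.ndarray],
) -> pd.Series:
    """Fraction of frames per replicate satisfying a threshold predicate.

    ``predicate`` is either an (operator, threshold) pair like ``("<", 2.5)``
    or a vectorised boolean callable.
    """
    if isinstance(predicate, tuple):
        op, thr = predicate
        func = lambda v: _PREDICATE_OPS[op](v, thr)  # noqa: E731
    else:
        func = predicate
    out = {}
    for rep, values in series_by_replicate.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise ValueError(f"replicate {rep!r} has no values")
        out[rep] = float(np.mean(func(v)))
    return pd.Series(out, name="fraction")


def circular_distance(a: float | np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """Shortest angular distance in degrees between two angles on the circle."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


@dataclass
class ComparisonResult:
    p_value: float
    method: str
    statistic: float
    warning: str | None = None


def compare_conditions(
    frac_a: Sequence[float],
    frac_b: Sequence[float],
    method: str = "exact-rank",
    n_resamples: int = 100_000,
    seed: int | None = None,
) -> ComparisonResult:
    """Two-sided comparison of replicate-level fractions between conditions.

    ``exact-rank`` enumerates all assignments of the pooled values to groups
    and computes the exact two-sided Mann–Whitney p-value (feasible for group
    sizes ≤ 12; ties handled by enumeration).  ``permutation`` runs a seeded
    Monte-Carlo permutation test on the difference of group means.
    """
    a = np.asarray(list(frac_a), dtype=float)
    b = np.asarray(list(frac_b), dtype=float)
    if a.size < 2 or b.size < 2:
        return ComparisonResult(1.0, method, np.nan, warning="groups too small for a meaningful p-value")
    if method == "exact-rank":
        def u_stat(x, y):
            return stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
        res = stats.permutation_test(
            (a, b), u_stat, permutation_type="independent",
            alternative="two-sided", n_resamples=np.inf,
        )
        return ComparisonResult(float(res.pvalue), method, float(res.statistic))
    if method == "permutation":
        rng = np.random.default_rng(seed)
        res = stats.permutation_test(
            (a, b), lambda x, y: np.mean(x) - np.mean(y),
            permutation_type="independent", alternative="two-sided",
            n_resamples=n_resamples, rng=rng,
        )
        return ComparisonResult(float(res.pvalue), method, float(res.statistic))
    raise ValueError(f"unknown method {method!r}")


def density_2d(
    x: Sequence[float], y: Sequence[float], bins: int | Sequence = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized 2-D histogram of two metric sequences (masses sum to 1).

    Returns (density, x_edges, y_edges).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    counts, xe, ye = np.histogram2d(x, y, bins=bins)
    return counts / counts.sum(), xe, ye
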