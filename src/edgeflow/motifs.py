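"""Edge-based network motifs: correlated fluctuation of connectivity metrics.

Per-epoch dPTE (directed edges) and PLV (undirected edges) form an
:class:`EdgeMetricSeries` — the fluctuation record of every edge of the
network across time. Correlating these columns against each other exposes
motifs: bundles of pathways whose information flow co-fluctuates
(dPTE x dPTE) and pathways whose flow tracks the network's functional
connectivity (dPTE x PLV). State contrasts difference the mean metric
between behavioural states edge by edge, and segment-shuffle surrogates
provide the null against which observed flow is judged.

Because dPTE is antisymmetric, the column of edge (a, b) is exactly the
negated column of (b, a); Pearson correlation between an edge and its
reverse is therefore exactly -1, and every correlation involving a reversed
edge flips sign.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import EpochNetworkMetrics, pair_metrics
from .exceptions import ValidationError
from .io import Band, Recording, bandpass, hilbert_phase, segment_epochs
from . import connectivity

__all__ = [
    "EdgeMetricSeries",
    "MotifCorrelation",
    "ContrastResult",
    "SurrogateNull",
    "build_edge_series",
    "node_disjoint_mask",
    "pool_edge_series",
    "dpte_dpte_correlation",
    "dpte_plv_correlation",
    "state_contrast",
    "count_changed_edges",
    "shuffle_surrogate_null",
]


@dataclass
class EdgeMetricSeries:
    """Per-epoch metric values for every edge of the network.

    ``dpte`` is epochs x directed edges (both orientations of every pair,
    lexicographic by (source index, target index)); ``plv`` is epochs x
    undirected edges (source index < target index).
    """

    regions: list[str]
    directed_edges: list[tuple[str, str]]
    undirected_edges: list[tuple[str, str]]
    dpte: np.ndarray
    plv: np.ndarray
    states: list[str]
    epoch_indices: list[int]

    @property
    def n_epochs(self) -> int:
        return self.dpte.shape[0]

    def rows_of(self, state: str) -> np.ndarray:
        mask = np.array([s == state for s in self.states])
        if not mask.any():
            raise ValidationError(f"no epochs with state {state!r}")
        return mask

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: epoch_index, state, source, target, metric, value."""
        rows = []
        for r, (state, idx) in enumerate(zip(self.states, self.epoch_indices)):
            for c, (a, b) in enumerate(self.directed_edges):
                rows.append((idx, state, a, b, "dpte", self.dpte[r, c]))
            for c, (a, b) in enumerate(self.undirected_edges):
                rows.append((idx, state, a, b, "plv", self.plv[r, c]))
        return pd.DataFrame(
            rows, columns=["epoch_index", "state", "source", "target", "metric", "value"]
        )


@dataclass
class MotifCorrelation:
    """Pearson correlation (and two-sided p) between edge metric columns."""

    r: np.ndarray
    p: np.ndarray
    row_edges: list[tuple[str, str]]
    col_edges: list[tuple[str, str]]
    n_epochs: int
    state: str = ""

    def thresholded(self, p_threshold: float) -> np.ndarray:
        """Non-destructive view: r where p < threshold, NaN elsewhere."""
        out = self.r.copy()
        out[~(self.p < p_threshold)] = np.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, re_ in enumerate(self.row_edges):
            for j, ce in enumerate(self.col_edges):
                rows.append((*re_, *ce, self.r[i, j], self.p[i, j]))
        return pd.DataFrame(
            rows,
            columns=["row_source", "row_target", "col_source", "col_target", "r", "p"],
        )

    @property
    def node_disjoint(self) -> np.ndarray:
        """Mask of cells whose two edges share no region.

        Edge pairs sharing a region are structurally dependent: their metric
        columns are functions of the same channel's phase realization, so
        their correlation is inflated even for completely independent
        channels. Only node-disjoint cells carry a calibrated null.
        """
        return node_disjoint_mask(self.row_edges, self.col_edges)


@dataclass
class ContrastResult:
    """Per-edge mean difference (state A - state B) with a t test."""

    edges: list[tuple[str, str]]
    mean_diff: np.ndarray
    statistic: np.ndarray
    pvalue: np.ndarray
    test: str
    n_a: int
    n_b: int
    metric: str
    state_a: str = ""
    state_b: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": [e[0] for e in self.edges],
                "target": [e[1] for e in self.edges],
                "mean_diff": self.mean_diff,
                "statistic": self.statistic,
                "pvalue": self.pvalue,
            }
        )

    def thresholded_network(
        self, p_threshold: float, magnitude_threshold: float = 0.0
    ) -> pd.DataFrame:
        """Edge list (source, target, weight) of significant net changes.

        Each unordered pair appears once, oriented along its positive mean
        net change.
        """
        frame = self.to_frame()
        frame = frame[
            (frame.pvalue < p_threshold) & (frame.mean_diff.abs() >= magnitude_threshold)
        ]
        if self.metric == "dpte":
            frame = frame[frame.mean_diff > 0]
        return frame.rename(columns={"mean_diff": "weight"})[
            ["source", "target", "weight"]
        ].reset_index(drop=True)


@dataclass
class SurrogateNull:
    """Null distribution of a network-mean metric under segment shuffling."""

    metric: str
    values: np.ndarray
    n_shuffles: int

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.values, q))


def pool_edge_series(
    series_list: list[EdgeMetricSeries], subjects: list[str] | None = None
) -> tuple[EdgeMetricSeries, pd.DataFrame]:
    """Pool epochs from several recordings (animals) into one series.

    Group-level analysis pools individual epochs across subjects; the
    returned frame additionally reports each subject's per-state mean of
    every directed edge, so both the pooled and the per-subject views are
    available. All recordings must share the region set.
    """
    if not series_list:
        raise ValidationError("no series supplied")
    regions = series_list[0].regions
    for s in series_list:
        if s.regions != regions or s.directed_edges != series_list[0].directed_edges:
            raise ValidationError("inconsistent region sets across subjects")
    if subjects is None:
        subjects = [f"subject_{i}" for i in range(len(series_list))]
    if len(subjects) != len(series_list):
        raise ValidationError("one subject label per series required")
    pooled = EdgeMetricSeries(
        regions=regions,
        directed_edges=list(series_list[0].directed_edges),
        undirected_edges=list(series_list[0].undirected_edges),
        dpte=np.vstack([s.dpte for s in series_list]),
        plv=np.vstack([s.plv for s in series_list]),
        states=[st for s in series_list for st in s.states],
        epoch_indices=[i for s in series_list for i in s.epoch_indices],
    )
    rows = []
    for subject, s in zip(subjects, series_list):
        for state in dict.fromkeys(s.states):
            mask = s.rows_of(state)
            for c, (a, b) in enumerate(s.directed_edges):
                rows.append(
                    (subject, state, a, b, float(s.dpte[mask, c].mean()))
                )
    per_subject = pd.DataFrame(
        rows, columns=["subject", "state", "source", "target", "mean_dpte"]
    )
    return pooled, per_subject


def node_disjoint_mask(
    row_edges: list[tuple[str, str]], col_edges: list[tuple[str, str]]
) -> np.ndarray:
    """Boolean matrix: True where row edge and column edge share no region."""
    return np.array(
        [[not (set(a) & set(b)) for b in col_edges] for a in row_edges]
    )


def build_edge_series(metrics: list[EpochNetworkMetrics]) -> EdgeMetricSeries:
    """Stack per-epoch network matrices into per-edge metric time courses."""
    if not metrics:
        raise ValidationError("no epoch metrics supplied")
    regions = metrics[0].regions
    for m in metrics:
        if m.regions != regions:
            raise ValidationError("inconsistent region sets across epochs")
    n = len(regions)
    directed = [(i, j) for i in range(n) for j in range(n) if i != j]
    undirected = [(i, j) for i in range(n) for j in range(i + 1, n)]
    dpte = np.array([[m.dpte_matrix[i, j] for i, j in directed] for m in metrics])
    plv = np.array([[m.plv_matrix[i, j] for i, j in undirected] for m in metrics])
    return EdgeMetricSeries(
        regions=regions,
        directed_edges=[(regions[i], regions[j]) for i, j in directed],
        undirected_edges=[(regions[i], regions[j]) for i, j in undirected],
        dpte=dpte,
        plv=plv,
        states=[m.state for m in metrics],
        epoch_indices=[m.epoch_index for m in metrics],
    )


def _pearson_cross(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise Pearson r and two-sided p between two column blocks."""
    n = a.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 epochs for correlation")
    am = a - a.mean(axis=0)
    bm = b - b.mean(axis=0)
    sa = np.sqrt((am**2).sum(axis=0))
    sb = np.sqrt((bm**2).sum(axis=0))
    dead_a, dead_b = sa == 0, sb == 0
    if dead_a.any() or dead_b.any():
        warnings.warn(
            "zero-variance metric column(s); correlations reported as NaN",
            RuntimeWarning,
            stacklevel=3,
        )
    sa[dead_a] = np.nan
    sb[dead_b] = np.nan
    r = (am.T @ bm) / np.outer(sa, sb)
    r = np.clip(r, -1.0, 1.0)
    # two-sided p from the exact null distribution of r (equivalent to the t test)
    dist = stats.beta(n / 2 - 1, n / 2 - 1, loc=-1, scale=2)
    with np.errstate(invalid="ignore"):
        p = 2 * dist.sf(np.abs(r))
    p = np.where(np.isnan(r), np.nan, np.minimum(p, 1.0))
    return r, p


def dpte_dpte_correlation(series: EdgeMetricSeries, state: str) -> MotifCorrelation:
    """Pearson correlation of dPTE fluctuations between every ordered edge pair.

    Antisymmetry is honoured exactly: correlations are computed once per
    unordered pair of edges and expanded by sign, so an edge against its own
    reverse is exactly -1 and r[(a,b),(c,d)] = -r[(b,a),(c,d)] to the bit.
    """
    rows = series.rows_of(state)
    x = series.dpte[rows]
    # canonical orientation = first appearance of the unordered pair
    canon: dict[frozenset, int] = {}
    col_pair = np.empty(len(series.directed_edges), dtype=np.int64)
    col_sign = np.empty(len(series.directed_edges))
    canon_cols = []
    for c, (a, b) in enumerate(series.directed_edges):
        key = frozenset((a, b))
        if key not in canon:
            canon[key] = len(canon_cols)
            canon_cols.append(c)
        col_pair[c] = canon[key]
        col_sign[c] = 1.0 if canon_cols[canon[key]] == c else -1.0
    xc = x[:, canon_cols]
    rc, pc = _pearson_cross(xc, xc)
    np.fill_diagonal(rc, 1.0)
    np.fill_diagonal(pc, 0.0)
    sign = np.outer(col_sign, col_sign)
    r = sign * rc[np.ix_(col_pair, col_pair)]
    p = pc[np.ix_(col_pair, col_pair)]
    return MotifCorrelation(
        r=r,
        p=p,
        row_edges=list(series.directed_edges),
        col_edges=list(series.directed_edges),
        n_epochs=int(rows.sum()),
        state=state,
    )


def dpte_plv_correlation(series: EdgeMetricSeries, state: str) -> MotifCorrelation:
    """Correlation of dPTE fluctuations (rows) with PLV fluctuations (columns)."""
    rows = series.rows_of(state)
    r, p = _pearson_cross(series.dpte[rows], series.plv[rows])
    return MotifCorrelation(
        r=r,
        p=p,
        row_edges=list(series.directed_edges),
        col_edges=list(series.undirected_edges),
        n_epochs=int(rows.sum()),
        state=state,
    )


def state_contrast(
    series: EdgeMetricSeries,
    state_a: str,
    state_b: str,
    metric: str = "dpte",
    test: str = "two-sample",
    adjust: str = "none",
) -> ContrastResult:
    """Per-edge mean difference (A - B) with a two-sample or paired t test.

    No multiple-testing correction by default; ``adjust="bh"`` applies
    Benjamini-Hochberg to the p-values.
    """
    if metric not in ("dpte", "plv"):
        raise ValidationError(f"metric must be 'dpte' or 'plv', got {metric!r}")
    values = series.dpte if metric == "dpte" else series.plv
    edges = series.directed_edges if metric == "dpte" else series.undirected_edges
    xa = values[series.rows_of(state_a)]
    xb = values[series.rows_of(state_b)]
    if xa.shape[0] < 2 or xb.shape[0] < 2:
        raise ValidationError("t test needs at least 2 epochs per state")
    if test == "two-sample":
        res = stats.ttest_ind(xa, xb, axis=0)
    elif test == "paired":
        if xa.shape[0] != xb.shape[0]:
            raise ValidationError(
                f"paired test needs equal epoch counts, got {xa.shape[0]} vs {xb.shape[0]}"
            )
        res = stats.ttest_rel(xa, xb, axis=0)
    else:
        raise ValidationError(f"unknown test {test!r}")
    pvalue = np.asarray(res.pvalue, dtype=np.float64)
    if adjust == "bh":
        pvalue = stats.false_discovery_control(pvalue, method="bh")
    elif adjust != "none":
        raise ValidationError(f"unknown adjustment {adjust!r}")
    return ContrastResult(
        edges=list(edges),
        mean_diff=xa.mean(axis=0) - xb.mean(axis=0),
        statistic=np.asarray(res.statistic, dtype=np.float64),
        pvalue=pvalue,
        test=test,
        n_a=xa.shape[0],
        n_b=xb.shape[0],
        metric=metric,
        state_a=state_a,
        state_b=state_b,
    )


def count_changed_edges(contrast: ContrastResult, magnitude_threshold: float) -> int:
    """Edges whose |mean metric change| meets the threshold.

    For dPTE contrasts the two orientations of a pair carry the same
    magnitude with opposite sign, so each unordered pair is counted once
    (along its direction of net change).
    """
    if magnitude_threshold <= 0:
        raise ValidationError("magnitude_threshold must be positive")
    diffs = contrast.mean_diff
    edges = contrast.edges
    if contrast.metric == "dpte":
        seen: set[frozenset] = set()
        count = 0
        for (a, b), d in zip(edges, diffs):
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            if abs(d) >= magnitude_threshold:
                count += 1
        return count
    return int(np.count_nonzero(np.abs(diffs) >= magnitude_threshold))


def shuffle_surrogate_null(
    rec: Recording,
    band: Band,
    metric: str = "dpte",
    n_shuffles: int = 1000,
    seed: int = 0,
    epoch_length: float = 10.0,
) -> SurrogateNull:
    """Null distribution of the network-mean metric under segment shuffling.

    The recording is cut into fixed-length segments; each shuffle permutes
    the temporal order of every channel's segments independently, which
    destroys cross-channel alignment while preserving each segment's
    spectral content. The metric is recomputed for every pair and aligned
    segment position, and the network mean is stored — one null value per
    shuffle. Deterministic under a fixed seed.
    """
    if metric not in ("dpte", "plv"):
        raise ValidationError(f"metric must be 'dpte' or 'plv', got {metric!r}")
    if rec.n_channels < 2:
        raise ValidationError("need at least 2 channels")
    win = int(round(epoch_length * rec.sampling_rate))
    n_segments = rec.n_samples // win
    if n_segments < 2:
        raise ValidationError("need at least 2 segments to shuffle")
    # phase of every band-passed segment, computed once
    from .io import Epoch  # local import to avoid cycle at module load

    phases = np.empty((rec.n_channels, n_segments), dtype=object)
    for ch, label in enumerate(rec.region_labels):
        for k in range(n_segments):
            ep = Epoch(
                rec.signal[ch, k * win : (k + 1) * win],
                rec.sampling_rate,
                label,
                "surrogate",
                k,
            )
            phases[ch, k] = hilbert_phase(bandpass(ep, band)).phase

    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(range(rec.n_channels), 2))
    values = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perms = [rng.permutation(n_segments) for _ in range(rec.n_channels)]
        acc = 0.0
        cnt = 0
        for k in range(n_segments):
            for i, j in pairs:
                pi = phases[i, perms[i][k]]
                pj = phases[j, perms[j][k]]
                if metric == "plv":
                    acc += connectivity.plv(pi, pj)
                else:
                    acc += pair_metrics(pi, pj).dpte_xy
                cnt += 1
        values[s] = acc / cnt
    return SurrogateNull(metric=metric, values=values, n_shuffles=n_shuffles)


def metrics_for_state(
    rec: Recording, band: Band, state: str, epoch_length: float = 10.0
) -> list[EpochNetworkMetrics]:
    """Convenience: epoch, band-pass, phase, and all-pairs metrics for one state."""
    from .connectivity import epoch_network_metrics

    epochs = segment_epochs(rec, epoch_length, state)
    labels = rec.region_labels
    n_epochs = len(epochs[labels[0]])
    out = []
    for k in range(n_epochs):
        series = [hilbert_phase(bandpass(epochs[label][k], band)) for label in labels]
        out.append(epoch_network_metrics(series))
    return out
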