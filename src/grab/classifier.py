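"""Relationship calls from a pair's identity-window track.

Five statistics summarise the per-window IBS track of a pair:

* ``n_high_p2`` — windows with P2 in (0.8, 1], capturing IBD2 tracts
  (full siblings and twins/duplicates carry many such windows);
* ``peak_flag`` — whether the P2 histogram peaks higher on (0.8, 1]
  than on (0, 0.8];
* ``n_iw`` — identity-window count; the IW *fraction* is ~1 for
  parent-offspring and halves with each additional degree;
* ``frac_contig_iw`` — fraction of IWs adjacent (same chromosome,
  consecutive window index) to another IW;
* ``max_run`` — longest within-chromosome run of consecutive IWs.

A fixed-order decision tree maps these to one of the labels
IT (twin/self), FS, PO, D2–D5, UD (related, degree unknown), UN
(unrelated).  Numeric thresholds are calibrated from labeled simulated
pairs with :func:`calibrate`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ibs_core import WindowIBS

LABELS = ("IT", "FS", "PO", "D2", "D3", "D4", "D5", "UD", "UN")

#: label -> degree (None where no degree is asserted)
LABEL_DEGREE: dict[str, int | None] = {
    "IT": 0,
    "FS": 1,
    "PO": 1,
    "D2": 2,
    "D3": 3,
    "D4": 4,
    "D5": 5,
    "UD": None,
    "UN": None,
}

#: classes calibrate() insists on seeing at least once
REQUIRED_CLASSES = ("IT", "FS", "PO", "D2", "D3", "D4", "D5", "UN")

HIGH_P2_EDGE = 0.8  # boundary of the "high P2" region
P2_BIN_WIDTH = 0.05  # histogram bin width for peak_flag


class InsufficientWindowsError(ValueError):
    """Too few retained windows to support a relationship call."""


class MissingClassError(ValueError):
    """A required relationship class is absent from training data."""


@dataclass(frozen=True)
class PairMetrics:
    n_windows: int
    n_high_p2: int
    peak_flag: bool
    n_iw: int
    frac_contig_iw: float
    max_run: int

    @property
    def iw_frac(self) -> float:
        return self.n_iw / self.n_windows if self.n_windows else 0.0

    @property
    def high_p2_frac(self) -> float:
        return self.n_high_p2 / self.n_windows if self.n_windows else 0.0


@dataclass(frozen=True)
class RelationshipCall:
    label: str | None
    degree: int | None = None

    def __post_init__(self) -> None:
        if self.label is not None:
            if self.label not in LABELS:
                raise ValueError(f"unknown label {self.label!r}")
            object.__setattr__(self, "degree", LABEL_DEGREE[self.label])


@dataclass(frozen=True)
class ThresholdSet:
    """Calibrated decision-tree thresholds.

    ``iw_frac_cuts`` are the (strictly decreasing) lower bounds of the
    IW fraction for PO, D2, D3, D4 and D5 in that order.
    """

    it_frac_min: float
    high_p2_min: float
    iw_frac_cuts: tuple[float, ...]
    contig_frac_min: float
    max_run_min: float
    min_windows: int = 100

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.iw_frac_cuts)
        if len(cuts) != 5:
            raise ValueError("iw_frac_cuts must have 5 entries (PO, D2..D5)")
        if any(b >= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("iw_frac_cuts must be strictly decreasing")
        if not all(0 <= c <= 1 for c in cuts):
            raise ValueError("iw_frac_cuts must lie in [0, 1]")
        object.__setattr__(self, "iw_frac_cuts", cuts)

    def save(self, path) -> None:
        lines = [
            f"it_frac_min={self.it_frac_min:.6g}",
            f"high_p2_min={self.high_p2_min:.6g}",
            "iw_frac_cuts=" + ",".join(f"{c:.6g}" for c in self.iw_frac_cuts),
            f"contig_frac_min={self.contig_frac_min:.6g}",
            f"max_run_min={self.max_run_min:.6g}",
            f"min_windows={self.min_windows}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "ThresholdSet":
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        return cls(
            it_frac_min=float(kv["it_frac_min"]),
            high_p2_min=float(kv["high_p2_min"]),
            iw_frac_cuts=tuple(float(x) for x in kv["iw_frac_cuts"].split(",")),
            contig_frac_min=float(kv["contig_frac_min"]),
            max_run_min=float(kv["max_run_min"]),
            min_windows=int(kv.get("min_windows", 100)),
        )


def default_thresholds() -> ThresholdSet:
    """Packaged defaults, calibrated on a seed-fixed simulated family."""
    from importlib.resources import files

    return ThresholdSet.load(files("grab") / "data" / "default_thresholds.txt")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _metrics_from_arrays(
    p2: np.ndarray,
    is_iw: np.ndarray,
    chrom_codes: np.ndarray,
    win_index: np.ndarray,
) -> PairMetrics:
    """Shared numeric core for :func:`pair_metrics` and the pipeline.

    Arrays cover the *retained* windows only, ordered by (chromosome,
    window index).  Adjacency requires the same chromosome code and a
    window-index difference of exactly 1, so a dropped window breaks a
    run, and chromosome boundaries never join.
    """
    n_windows = len(p2)
    if n_windows == 0:
        raise InsufficientWindowsError("empty window track")

    high = (p2 > HIGH_P2_EDGE) & (p2 <= 1.0)
    n_high_p2 = int(high.sum())

    # Histogram over (0, 1] with fixed-width bins; P2 == 0 is outside
    # the domain and ignored.  bin k covers (k*w, (k+1)*w].
    nbins = int(round(1.0 / P2_BIN_WIDTH))
    pos = p2[p2 > 0]
    bins = np.minimum(np.ceil(pos / P2_BIN_WIDTH).astype(int) - 1, nbins - 1)
    counts = np.bincount(bins, minlength=nbins)
    split = int(round(HIGH_P2_EDGE / P2_BIN_WIDTH))
    peak_flag = bool(counts[split:].max(initial=0) > counts[:split].max(initial=0))

    iw = np.asarray(is_iw, dtype=bool)
    n_iw = int(iw.sum())

    adjacent_next = np.zeros(n_windows, dtype=bool)
    if n_windows > 1:
        adjacent_next[:-1] = (chrom_codes[1:] == chrom_codes[:-1]) & (
            win_index[1:] - win_index[:-1] == 1
        )
    both_iw = np.zeros(n_windows, dtype=bool)
    both_iw[:-1] = adjacent_next[:-1] & iw[:-1] & iw[1:]
    # an IW is contiguous if joined to its predecessor or successor
    contig = np.zeros(n_windows, dtype=bool)
    contig[:-1] |= both_iw[:-1]
    contig[1:] |= both_iw[:-1]
    frac_contig = float(contig.sum() / n_iw) if n_iw else 0.0

    # longest run of IWs joined by adjacency
    max_run = 0
    run = 0
    for i in range(n_windows):
        if iw[i]:
            run = run + 1 if (i > 0 and both_iw[i - 1]) else 1
            max_run = max(max_run, run)
        else:
            run = 0

    return PairMetrics(
        n_windows=n_windows,
        n_high_p2=n_high_p2,
        peak_flag=peak_flag,
        n_iw=n_iw,
        frac_contig_iw=frac_contig,
        max_run=max_run,
    )


def pair_metrics(track: list[WindowIBS]) -> PairMetrics:
    """Compute the five classification statistics from a window track."""
    if not track:
        raise InsufficientWindowsError("empty window track")
    chroms = [w.window.chrom for w in track]
    codes = np.unique(np.array(chroms, dtype=object), return_inverse=True)[1]
    return _metrics_from_arrays(
        p2=np.array([w.P2 for w in track]),
        is_iw=np.array([w.is_iw for w in track]),
        chrom_codes=codes,
        win_index=np.array([w.window.index for w in track]),
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify(m: PairMetrics, t: ThresholdSet) -> RelationshipCall:
    """Run the decision tree on one pair's metrics.

    Order: (1) IT when high-P2 windows cover nearly the whole genome;
    (2) FS when enough high-P2 windows exist or the P2 histogram peaks
    high — the IBD2-tract count is the primary sibling evidence, the
    peak comparison supplements it (on synthetic founder genomes the
    central IBS1 mode of the window-P2 histogram can out-peak the IBD2
    mode even for true siblings); (3) otherwise the IW fraction is
    mapped through the degree cutpoints to PO/D2..D5; (4) below the D5
    cut, contiguity evidence separates UD from UN.
    """
    if m.n_windows < t.min_windows:
        raise InsufficientWindowsError(
            f"{m.n_windows} retained windows < min_windows={t.min_windows}"
        )
    if m.high_p2_frac >= t.it_frac_min:
        return RelationshipCall("IT")
    if m.n_high_p2 >= t.high_p2_min or m.peak_flag:
        return RelationshipCall("FS")
    f = m.iw_frac
    for label, cut in zip(("PO", "D2", "D3", "D4", "D5"), t.iw_frac_cuts):
        if f >= cut:
            return RelationshipCall(label)
    if m.frac_contig_iw >= t.contig_frac_min or m.max_run >= t.max_run_min:
        return RelationshipCall("UD")
    return RelationshipCall("UN")


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def _best_cut(hi: np.ndarray, lo: np.ndarray) -> float:
    """1-D decision stump: threshold c maximising
    #(hi >= c) + #(lo < c), ties broken toward the midpoint between the
    class ranges.  Perfectly separated classes therefore yield the
    midpoint of the gap."""
    hi = np.asarray(hi, dtype=float)
    lo = np.asarray(lo, dtype=float)
    vals = np.unique(np.concatenate([hi, lo]))
    if len(vals) == 1:
        return float(vals[0])
    candidates = (vals[:-1] + vals[1:]) / 2
    scores = np.array(
        [(hi >= c).sum() + (lo < c).sum() for c in candidates], dtype=float
    )
    best = scores == scores.max()
    anchor = (hi.min() + lo.max()) / 2
    cand = candidates[best]
    return float(cand[np.argmin(np.abs(cand - anchor))])


def _degree_of_truth(label: str) -> int | None:
    """Degree for a truth label; handles D6, D7, ... beyond the call set."""
    if label in LABEL_DEGREE:
        return LABEL_DEGREE[label]
    if label.startswith("D") and label[1:].isdigit():
        return int(label[1:])
    return None


def calibrate(
    labeled: list[tuple[PairMetrics, str]],
    *,
    min_windows: int = 100,
    it_floor: float = 0.95,
) -> ThresholdSet:
    """Fit decision-tree thresholds to labeled training pairs.

    Truth labels may include deeper classes (D6, D7, ...); those pairs,
    together with explicit UD labels, calibrate the UD-vs-UN contiguity
    gates.  Every class in :data:`REQUIRED_CLASSES` must be present.
    Deterministic given the input.
    """
    groups: dict[str, list[PairMetrics]] = {}
    for m, label in labeled:
        groups.setdefault(label, []).append(m)
    for cls in REQUIRED_CLASSES:
        if cls not in groups:
            raise MissingClassError(f"training data lacks class {cls}")

    def stat(labels, fn):
        return np.array([fn(m) for lb in labels for m in groups.get(lb, [])])

    non_it = [lb for lb in groups if lb != "IT"]
    it_cut = _best_cut(
        stat(["IT"], lambda m: m.high_p2_frac),
        stat(non_it, lambda m: m.high_p2_frac),
    )
    # twin/self coverage is near-total by definition; keep a high floor
    it_frac_min = max(it_floor, it_cut)

    non_fs = [lb for lb in groups if lb not in ("IT", "FS")]
    high_p2_min = _best_cut(
        stat(["FS"], lambda m: float(m.n_high_p2)),
        stat(non_fs, lambda m: float(m.n_high_p2)),
    )

    deeper = sorted(
        (lb for lb in groups if (_degree_of_truth(lb) or 0) >= 6 or lb == "UD"),
    )
    degree_seq = ["PO", "D2", "D3", "D4", "D5"]
    cuts = []
    for i, lb in enumerate(degree_seq):
        below = degree_seq[i + 1 :]
        if i == len(degree_seq) - 1:
            below = deeper + ["UN"]
        cuts.append(
            _best_cut(
                stat([lb], lambda m: m.iw_frac),
                stat(below, lambda m: m.iw_frac),
            )
        )
    # enforce strict decrease (overlapping classes can produce ties)
    for i in range(1, 5):
        if cuts[i] >= cuts[i - 1]:
            cuts[i] = np.nextafter(cuts[i - 1], 0.0)

    un_frac = stat(["UN"], lambda m: m.frac_contig_iw)
    un_run = stat(["UN"], lambda m: float(m.max_run))
    if deeper:
        contig_frac_min = _best_cut(stat(deeper, lambda m: m.frac_contig_iw), un_frac)
        max_run_min = _best_cut(stat(deeper, lambda m: float(m.max_run)), un_run)
    else:
        contig_frac_min = min(1.0, float(un_frac.max()) + 0.05)
        max_run_min = float(un_run.max()) + 1.0

    return ThresholdSet(
        it_frac_min=float(it_frac_min),
        high_p2_min=float(high_p2_min),
        iw_frac_cuts=tuple(float(c) for c in cuts),
        contig_frac_min=float(contig_frac_min),
        max_run_min=float(max_run_min),
        min_windows=min_windows,
    )


# ---------------------------------------------------------------------------
# evaluation helpers
# ---------------------------------------------------------------------------


def within_one_degree(true_label: str, pred: RelationshipCall) -> bool:
    """Whether a prediction is within one degree of the truth.

    Exact matches count; otherwise both degrees must exist and differ
    by at most 1, except that a UD prediction counts for truths of 5th
    degree or deeper (related-without-degree is the adjacent outcome
    beyond D5).
    """
    if pred.label == true_label:
        return True
    td = _degree_of_truth(true_label)
    if pred.label == "UD":
        return td is not None and td >= 5
    if td is None or pred.degree is None:
        return False
    return abs(td - pred.degree) <= 1
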