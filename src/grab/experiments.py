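"""Replicate-family simulation studies for calibration and validation.

A *study* simulates several replicate families on a shared site panel
(so founders of different replicates form unrelated pairs), calibrates
the classification tree on the first family, and classifies selected
pair classes in the held-out families.  This is the experiment design
used to validate the classifier: train on one family, evaluate on the
rest, with unrelated pairs drawn across replicates.

Study defaults are the desk-scale WGS condition used throughout the
package: the GRCh37 autosomes, 1.5 million biallelic SNVs, 1 Mb
windows (see docs/methods.md for the choice of site count).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from . import classifier
from .classifier import PairMetrics, ThresholdSet
from .ibs_core import DEFAULT_WINDOW_SIZE, ErrorModelConfig, WindowIndex, make_windows
from .pedigree import Pedigree, default_family_pedigree
from .pipeline import pair_metrics_fast
from .simulate import SimConfig, apply_error, gene_drop, make_site_panel, simulate_founders

DEFAULT_STUDY_SITES = 1_500_000


@dataclass
class StudyResult:
    """Outcome of one train-on-one, test-on-rest replicate study."""

    thresholds: ThresholdSet
    se: float
    #: (metrics, truth label) for every training-family pair incl. self
    train_records: list[tuple[PairMetrics, str]]
    #: truth label -> predicted labels over held-out family pairs
    eval_predictions: dict[str, list[str]] = field(default_factory=dict)
    #: predicted labels for cross-family founder (unrelated) pairs
    unrelated_predictions: list[str] = field(default_factory=list)

    def accuracy(self, label: str) -> float:
        preds = self.eval_predictions[label]
        return sum(p == label for p in preds) / len(preds)

    def related_fraction(self, label: str) -> float:
        """Fraction of held-out pairs of a class called related (non-UN)."""
        preds = self.eval_predictions[label]
        return sum(p != "UN" for p in preds) / len(preds)

    def unrelated_accuracy(self) -> float:
        preds = self.unrelated_predictions
        return sum(p == "UN" for p in preds) / len(preds)

    def n_eval(self, label: str) -> int:
        return len(self.eval_predictions[label])


def _classify_label(m: PairMetrics, thresholds: ThresholdSet) -> str:
    try:
        return classifier.classify(m, thresholds).label
    except classifier.InsufficientWindowsError:
        return "NA"


def run_relationship_study(
    seed: int,
    *,
    se: float = 0.0,
    p0_cutoff: float | None = None,
    n_sites: int = DEFAULT_STUDY_SITES,
    n_families: int = 5,
    eval_labels: tuple[str, ...] = ("FS", "PO", "D2"),
    n_unrelated_pairs: int = 100,
    window_size: int = DEFAULT_WINDOW_SIZE,
    min_sites: int = 10,
    pedigree: Pedigree | None = None,
) -> StudyResult:
    """Simulate replicate families, calibrate on the first, evaluate the rest.

    Parameters mirror the validation experiment: ``n_families``
    replicates of the packaged 26-member pedigree on one shared site
    panel, genotypes perturbed at per-genotype error rate ``se`` with
    the identity-window cutoff taken from the published schedule
    (or overridden via ``p0_cutoff``).  ``eval_labels`` selects which
    truth classes are classified in the held-out families;
    ``n_unrelated_pairs`` cross-family founder pairs are classified as
    the unrelated test set.  Everything is deterministic given ``seed``.
    """
    ped = pedigree if pedigree is not None else default_family_pedigree()
    cfg = SimConfig(n_sites=n_sites, se=se, seed=seed)
    ecfg = ErrorModelConfig(se=se, p0_cutoff=p0_cutoff)

    ss = np.random.SeedSequence(seed)
    rng_panel, *rng_fams = [np.random.default_rng(s) for s in ss.spawn(n_families + 1)]
    panel = make_site_panel(cfg, rng_panel)
    windows = make_windows(cfg.chrom_lengths, window_size)
    widx = WindowIndex(panel.chrom, panel.pos, windows)

    truth = ped.pair_labels(include_self=True)
    founder_ids = ped.founders

    train_records: list[tuple[PairMetrics, str]] = []
    eval_preds: dict[str, list[str]] = defaultdict(list)
    founder_calls: list[np.ndarray] = []  # per family: (n_sites, n_founders)

    fam_gms = []
    for k in range(n_families):
        rng = rng_fams[k]
        founders = simulate_founders(cfg, len(founder_ids), rng, panel=panel, ids=founder_ids)
        dip = gene_drop(ped, founders, cfg, rng)
        gm = apply_error(dip, se, rng)
        fam_gms.append(gm)
        founder_calls.append(
            np.stack([gm.column(f) for f in founder_ids], axis=1)
        )

    # calibrate on family 0 using all pairs (self pairs supply IT)
    gm0 = fam_gms[0]
    for a, b, label in truth:
        m = pair_metrics_fast(gm0, a, b, windows, ecfg, min_sites=min_sites, widx=widx)
        train_records.append((m, label))
    thresholds = classifier.calibrate(train_records)

    # held-out families
    wanted = set(eval_labels)
    for gm in fam_gms[1:]:
        for a, b, label in truth:
            if label not in wanted:
                continue
            m = pair_metrics_fast(gm, a, b, windows, ecfg, min_sites=min_sites, widx=widx)
            eval_preds[label].append(_classify_label(m, thresholds))

    # unrelated pairs: founders of distinct replicate families
    un_preds: list[str] = []
    if n_unrelated_pairs > 0 and n_families > 1:
        rng_un = np.random.default_rng(ss.spawn(1)[0])
        n_f = len(founder_ids)
        seen = set()
        while len(un_preds) < n_unrelated_pairs:
            f1, f2 = rng_un.choice(n_families, size=2, replace=False)
            i, j = rng_un.integers(n_f), rng_un.integers(n_f)
            key = (int(f1), int(i), int(f2), int(j))
            if key in seen:
                continue
            seen.add(key)
            m = _metrics_from_cols(
                founder_calls[f1][:, i], founder_calls[f2][:, j],
                widx, ecfg, min_sites,
            )
            un_preds.append(_classify_label(m, thresholds))

    return StudyResult(
        thresholds=thresholds,
        se=se,
        train_records=train_records,
        eval_predictions=dict(eval_preds),
        unrelated_predictions=un_preds,
    )


def _metrics_from_cols(ga, gb, widx, ecfg, min_sites) -> PairMetrics:
    n0, _n1, n2, n = widx.pair_counts(ga, gb)
    retained = n >= max(min_sites, 1)
    n_r = n[retained]
    p0 = n0[retained] / n_r
    p2 = n2[retained] / n_r
    return classifier._metrics_from_arrays(
        p2=p2,
        is_iw=np.asarray(ecfg.window_is_iw(p0)),
        chrom_codes=widx.chrom_codes[retained],
        win_index=widx.win_index[retained],
    )


def count_nonempty_windows(
    n_sites: int,
    seed: int,
    *,
    chrom_lengths: dict[str, int] | None = None,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> int:
    """Windows containing >=1 SNV after uniform placement of ``n_sites``.

    The WGS-density check: segmenting a ~3.5M-site callset over the
    human autosomes into 1 Mb windows leaves essentially no window
    empty, giving >2700 informative windows.
    """
    from .genomes import GRCH37_AUTOSOMES

    lengths = chrom_lengths or GRCH37_AUTOSOMES
    rng = np.random.default_rng(seed)
    cfg = SimConfig(n_sites=n_sites, chrom_lengths=dict(lengths), seed=seed)
    panel = make_site_panel(cfg, rng)
    windows = make_windows(dict(lengths), window_size)
    widx = WindowIndex(panel.chrom, panel.pos, windows)
    return int((widx.site_counts > 0).sum())
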