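"""High-level glue: genotype matrix in, relationship calls out.

The per-pair work is three bincounts over a shared site-to-window
index, so classifying hundreds of pairs on a WGS-scale callset stays
cheap.  Pairs with missing calls fall back to per-pair site filtering.
"""

from __future__ import annotations

import numpy as np

from .classifier import (
    InsufficientWindowsError,
    PairMetrics,
    RelationshipCall,
    ThresholdSet,
    _metrics_from_arrays,
    classify,
    pair_metrics,
)
from .formats_io import MISSING, GenotypeMatrix, filter_pair_sites
from .ibs_core import (
    ErrorModelConfig,
    WindowIndex,
    WindowSpec,
    window_ibs,
)


def window_index_for(gm: GenotypeMatrix, windows: list[WindowSpec]) -> WindowIndex:
    return WindowIndex(gm.chrom, gm.pos, windows)


def pair_metrics_fast(
    gm: GenotypeMatrix,
    a: str,
    b: str,
    windows: list[WindowSpec],
    cfg: ErrorModelConfig,
    *,
    min_sites: int = 10,
    widx: WindowIndex | None = None,
) -> PairMetrics:
    """Window track metrics for one pair.

    Uses the shared :class:`WindowIndex` when both samples are fully
    called; otherwise filters to co-called sites first.
    """
    ga = gm.column(a)
    gb = gm.column(b)
    if (ga == MISSING).any() or (gb == MISSING).any():
        pair_gm = filter_pair_sites(gm, a, b)
        two = GenotypeMatrix(
            chrom=pair_gm.chrom,
            pos=pair_gm.pos,
            ref=pair_gm.ref,
            alt=pair_gm.alt,
            samples=[a, b],
            calls=np.stack([pair_gm.column(a), pair_gm.column(b)], axis=1),
        )
        return pair_metrics(window_ibs(two, windows, cfg, min_sites=min_sites))

    if widx is None:
        widx = WindowIndex(gm.chrom, gm.pos, windows)
    n0, _n1, n2, n = widx.pair_counts(ga, gb)
    retained = n >= max(min_sites, 1)
    if not retained.any():
        raise InsufficientWindowsError(
            f"no window reaches min_sites={min_sites} for pair ({a}, {b})"
        )
    n_r = n[retained]
    p0 = n0[retained] / n_r
    p2 = n2[retained] / n_r
    return _metrics_from_arrays(
        p2=p2,
        is_iw=np.asarray(cfg.window_is_iw(p0)),
        chrom_codes=widx.chrom_codes[retained],
        win_index=widx.win_index[retained],
    )


def estimate_pairs(
    gm: GenotypeMatrix,
    pairs: list[tuple[str, str]],
    windows: list[WindowSpec],
    cfg: ErrorModelConfig,
    thresholds: ThresholdSet,
    *,
    min_sites: int = 10,
) -> list[tuple[tuple[str, str], PairMetrics, RelationshipCall]]:
    """Metrics + relationship call for each requested pair.

    Pairs failing the retained-window gate get a no-label call.
    """
    widx = WindowIndex(gm.chrom, gm.pos, windows)
    out = []
    for a, b in pairs:
        m = pair_metrics_fast(
            gm, a, b, windows, cfg, min_sites=min_sites, widx=widx
        )
        try:
            call = classify(m, thresholds)
        except InsufficientWindowsError:
            call = RelationshipCall(label=None)
        out.append(((a, b), m, call))
    return out


def all_pairs(samples: list[str], include_self: bool = False) -> list[tuple[str, str]]:
    """Lexicographic sample pairs, each unordered pair reported once."""
    ids = sorted(samples)
    out = [(s, s) for s in ids] if include_self else []
    for i, a in enumerate(ids):
        out.extend((a, b) for b in ids[i + 1 :])
    return out
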