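"""Windowed identity-by-state statistics for a pair of genomes.

The genome is tiled with non-overlapping fixed-size windows (1 Mb for
WGS callsets, 2 Mb for genotyping-array density).  For each window the
fractions of sites in the three IBS states are computed:

* IBS2 — identical genotypes,
* IBS1 — exactly one shared allele,
* IBS0 — opposite homozygotes (no allele in common),

written P2, P1, P0.  A window is an *identity window* (IW) when its P0
falls below an error-rate-dependent cutoff: sharing at least one
haplotype across a window forbids IBS0 there, up to genotyping error,
so low-P0 windows evidence identity by descent.

The cutoff schedule as a function of the per-genotype error rate SE is
anchored at (SE, cutoff) = (0, 0), (0.001, 0.004), (0.005, 0.01),
(0.01, 0.015) and interpolated linearly in between.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats_io import MISSING, GenotypeMatrix
from .genomes import chrom_sort_key

DEFAULT_WINDOW_SIZE = 1_000_000  # WGS
ARRAY_WINDOW_SIZE = 2_000_000  # genotyping panels

_SE_ANCHORS = np.array([0.0, 0.001, 0.005, 0.01])
_CUTOFF_ANCHORS = np.array([0.0, 0.004, 0.01, 0.015])


@dataclass(frozen=True)
class WindowSpec:
    """Half-open window [start, end) on 1-based coordinates."""

    chrom: str
    start: int  # 1-based, inclusive
    end: int  # exclusive
    index: int  # ordinal within chromosome


@dataclass(frozen=True)
class WindowIBS:
    window: WindowSpec
    n0: int
    n1: int
    n2: int
    n: int
    P0: float
    P1: float
    P2: float
    is_iw: bool


@dataclass(frozen=True)
class ErrorModelConfig:
    """Per-genotype error rate and the IW threshold on P0.

    If ``p0_cutoff`` is None it is taken from the published schedule
    via :func:`p0_cutoff_for`.
    """

    se: float = 0.0
    p0_cutoff: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.se < 0.5:
            raise ValueError(f"se must be in [0, 0.5), got {self.se}")
        if self.p0_cutoff is None:
            object.__setattr__(self, "p0_cutoff", p0_cutoff_for(self.se))

    def window_is_iw(self, p0: float | np.ndarray):
        """IW rule: P0 < cutoff (strict); at cutoff 0, P0 == 0 qualifies.

        The strict inequality is degenerate at cutoff 0 (error-free
        data would never yield an IW), so the zero-cutoff case uses
        P0 <= 0 instead.
        """
        if self.p0_cutoff == 0:
            return p0 <= 0
        return p0 < self.p0_cutoff


def p0_cutoff_for(se: float) -> float:
    """IW cutoff on P0 for a per-genotype error rate ``se``.

    Returns the published schedule at its four anchor points and a
    monotone piecewise-linear interpolation elsewhere; above the last
    anchor the final segment's unit slope is continued.
    """
    if not 0 <= se < 0.5:
        raise ValueError(f"se must be in [0, 0.5), got {se}")
    if se > _SE_ANCHORS[-1]:
        return float(_CUTOFF_ANCHORS[-1] + (se - _SE_ANCHORS[-1]))
    return float(np.interp(se, _SE_ANCHORS, _CUTOFF_ANCHORS))


def ibs_state(ga: int, gb: int) -> int:
    """IBS state of one site: 2 if genotypes identical, 0 if opposite
    homozygotes, 1 otherwise.  Inputs must be called (0, 1 or 2)."""
    if ga not in (0, 1, 2) or gb not in (0, 1, 2):
        raise ValueError(
            f"ibs_state requires called genotypes in {{0,1,2}}, got ({ga}, {gb})"
        )
    return 2 - abs(ga - gb)


def ibs_states(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """Vectorised :func:`ibs_state`; both arrays must be fully called."""
    ga = np.asarray(ga)
    gb = np.asarray(gb)
    if (ga == MISSING).any() or (gb == MISSING).any():
        raise ValueError("ibs_states requires fully called genotypes; pre-filter")
    return 2 - np.abs(ga.astype(np.int8) - gb.astype(np.int8))


def make_windows(chrom_lengths: dict[str, int], window_size: int) -> list[WindowSpec]:
    """Tile each chromosome with half-open ``window_size`` windows.

    The last window per chromosome may be short; a site at 1-based
    position ``pos`` falls in window ``(pos - 1) // window_size``.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if not chrom_lengths:
        raise ValueError("chrom_lengths is empty")
    windows: list[WindowSpec] = []
    for chrom in sorted(chrom_lengths, key=chrom_sort_key):
        length = chrom_lengths[chrom]
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {chrom}")
        n_win = -(-length // window_size)  # ceil
        for k in range(n_win):
            start = k * window_size + 1
            end = min((k + 1) * window_size, length) + 1
            windows.append(WindowSpec(chrom=chrom, start=start, end=end, index=k))
    return windows


class WindowIndex:
    """Site-to-window assignment shared across pairs on one site panel.

    Precomputes, for a fixed (chrom, pos) panel and window list, the
    per-site window ordinal plus per-window bookkeeping arrays, so that
    per-pair work reduces to three bincounts.
    """

    def __init__(
        self,
        chrom: np.ndarray,
        pos: np.ndarray,
        windows: list[WindowSpec],
    ) -> None:
        self.windows = windows
        self.n_windows = len(windows)
        uid_of = {(w.chrom, w.index): i for i, w in enumerate(windows)}
        size_of: dict[str, int] = {}
        for w in windows:
            span = w.end - w.start
            if span > size_of.get(w.chrom, 0):
                size_of[w.chrom] = span
        # nominal tile size per chromosome = widest window (the last
        # window may be short)
        site_uid = np.full(len(pos), -1, dtype=np.int64)
        for c in np.unique(np.asarray(chrom, dtype=object)):
            sel = np.nonzero(chrom == c)[0]
            ws = size_of.get(c)
            if ws is None:
                continue  # chromosome absent from the window list
            idx = (pos[sel] - 1) // ws
            for s, k in zip(sel, idx):
                site_uid[s] = uid_of.get((c, int(k)), -1)
        self.site_uid = site_uid
        self.in_windows = site_uid >= 0
        # adjacency: window uid i and i+1 are index-consecutive on the
        # same chromosome (never across a chromosome boundary)
        chrom_arr = np.array([w.chrom for w in windows], dtype=object)
        idx_arr = np.array([w.index for w in windows])
        self.chrom_codes = np.unique(chrom_arr, return_inverse=True)[1]
        self.win_index = idx_arr
        self.site_counts = np.bincount(
            site_uid[self.in_windows], minlength=self.n_windows
        )

    def pair_counts(self, ga: np.ndarray, gb: np.ndarray):
        """Per-window IBS0/1/2 counts for one fully-called pair."""
        states = ibs_states(ga, gb)
        uid = self.site_uid
        m = self.in_windows
        n0 = np.bincount(uid[m & (states == 0)], minlength=self.n_windows)
        n2 = np.bincount(uid[m & (states == 2)], minlength=self.n_windows)
        n = np.bincount(uid[m], minlength=self.n_windows)
        n1 = n - n0 - n2
        return n0, n1, n2, n


def window_ibs(
    gm_pair: GenotypeMatrix,
    windows: list[WindowSpec],
    cfg: ErrorModelConfig,
    min_sites: int = 10,
) -> list[WindowIBS]:
    """Per-window IBS fractions and IW calls for a two-sample matrix.

    ``gm_pair`` must contain exactly the two samples of interest with
    no missing calls (see :func:`grab.formats_io.filter_pair_sites`).
    Windows with fewer than ``min_sites`` sites are omitted.
    """
    if gm_pair.n_samples != 2:
        raise ValueError(
            f"window_ibs expects a 2-sample matrix, got {gm_pair.n_samples}"
        )
    widx = WindowIndex(gm_pair.chrom, gm_pair.pos, windows)
    n0, n1, n2, n = widx.pair_counts(gm_pair.calls[:, 0], gm_pair.calls[:, 1])
    retained = n >= max(min_sites, 1)
    if not retained.any():
        raise ValueError(
            "insufficient marker density: no window reaches "
            f"min_sites={min_sites}"
        )
    out: list[WindowIBS] = []
    for i in np.nonzero(retained)[0]:
        ni = int(n[i])
        p0 = n0[i] / ni
        p1 = n1[i] / ni
        p2 = n2[i] / ni
        out.append(
            WindowIBS(
                window=windows[i],
                n0=int(n0[i]),
                n1=int(n1[i]),
                n2=int(n2[i]),
                n=ni,
                P0=p0,
                P1=p1,
                P2=p2,
                is_iw=bool(cfg.window_is_iw(p0)),
            )
        )
    return out
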