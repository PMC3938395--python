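"""Reading and writing genotype data and results tables.

Genotypes are held in a :class:`GenotypeMatrix`: biallelic SNV sites by
samples, each call coded as the count of alternate alleles (0, 1, 2) or
:data:`MISSING` (-1) when any allele of the call is unknown.  Phase is
accepted on input but discarded — the downstream identity-by-state
statistics are phase-free.

Supported input formats: VCF 4.x (optionally gzipped, read through
cyvcf2), PLINK PED+MAP and TPED (whitespace-delimited text).  Records
that are not biallelic SNVs are dropped with a logged count.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomes import chrom_sort_key, is_autosome

log = logging.getLogger(__name__)

MISSING: int = -1

_BASES = {"A", "C", "G", "T"}

RESULT_COLUMNS = [
    "sample1",
    "sample2",
    "n_windows",
    "n_high_p2",
    "peak_flag",
    "n_iw",
    "frac_contig_iw",
    "max_run",
    "predicted_label",
]


class FormatError(ValueError):
    """Input file does not parse under the named standard."""


class EmptyInputError(ValueError):
    """No biallelic SNVs survived parsing/filtering."""


@dataclass(frozen=True)
class VariantSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str


@dataclass
class GenotypeMatrix:
    """Biallelic SNV genotypes for sites x samples.

    ``calls`` is an int8 array of shape (n_sites, n_samples) holding
    alt-allele counts, with MISSING (-1) for no-calls.  Sites are sorted
    by (chrom, pos) and unique per (chrom, pos).
    """

    chrom: np.ndarray  # object/str, per site
    pos: np.ndarray  # int64, per site
    ref: np.ndarray
    alt: np.ndarray
    samples: list[str]
    calls: np.ndarray  # int8, (n_sites, n_samples)
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.pos)} sites x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0, 1, 2 or MISSING")
        self._index = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sites(self) -> list[VariantSite]:
        return [
            VariantSite(c, int(p), r, a)
            for c, p, r, a in zip(self.chrom, self.pos, self.ref, self.alt)
        ]

    def sample_index(self, sample: str) -> int:
        try:
            return self._index[sample]
        except KeyError:
            raise KeyError(f"unknown sample ID: {sample!r}") from None

    def column(self, sample: str) -> np.ndarray:
        return self.calls[:, self.sample_index(sample)]

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            samples=list(self.samples),
            calls=self.calls[mask],
        )


def _finalize(
    chroms: list[str],
    poss: list[int],
    refs: list[str],
    alts: list[str],
    samples: list[str],
    calls: np.ndarray,
    chrom_include,
    n_dropped: int,
    source: str,
) -> GenotypeMatrix:
    """Sort, deduplicate and chromosome-filter parsed records."""
    if n_dropped:
        log.info("%s: dropped %d non-biallelic-SNV record(s)", source, n_dropped)
    chrom_arr = np.asarray(chroms, dtype=object)
    pos_arr = np.asarray(poss, dtype=np.int64)
    ref_arr = np.asarray(refs, dtype=object)
    alt_arr = np.asarray(alts, dtype=object)

    if chrom_include == "autosomes":
        keep = np.fromiter((is_autosome(c) for c in chrom_arr), bool, len(chrom_arr))
    elif chrom_include is None:
        keep = np.ones(len(chrom_arr), dtype=bool)
    else:
        allowed = set(chrom_include)
        keep = np.fromiter((c in allowed for c in chrom_arr), bool, len(chrom_arr))
    chrom_arr, pos_arr, ref_arr, alt_arr = (
        chrom_arr[keep],
        pos_arr[keep],
        ref_arr[keep],
        alt_arr[keep],
    )
    calls = calls[keep]

    if len(pos_arr) == 0:
        raise EmptyInputError(f"{source}: no biallelic SNVs after parsing/filtering")

    order = sorted(
        range(len(pos_arr)), key=lambda i: (chrom_sort_key(chrom_arr[i]), pos_arr[i])
    )
    order = np.asarray(order)
    chrom_arr, pos_arr, ref_arr, alt_arr = (
        chrom_arr[order],
        pos_arr[order],
        ref_arr[order],
        alt_arr[order],
    )
    calls = calls[order]

    # Duplicate (chrom, pos): keep the first, warn.
    seen: set[tuple[str, int]] = set()
    uniq = np.ones(len(pos_arr), dtype=bool)
    for i, (c, p) in enumerate(zip(chrom_arr, pos_arr)):
        key = (c, int(p))
        if key in seen:
            uniq[i] = False
        seen.add(key)
    if not uniq.all():
        log.warning(
            "%s: %d duplicated (chrom, pos) site(s); keeping first occurrence",
            source,
            int((~uniq).sum()),
        )
        chrom_arr, pos_arr, ref_arr, alt_arr = (
            chrom_arr[uniq],
            pos_arr[uniq],
            ref_arr[uniq],
            alt_arr[uniq],
        )
        calls = calls[uniq]

    return GenotypeMatrix(
        chrom=chrom_arr,
        pos=pos_arr,
        ref=ref_arr,
        alt=alt_arr,
        samples=samples,
        calls=np.ascontiguousarray(calls, dtype=np.int8),
    )


def _read_vcf(path: Path, chrom_include) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required to read VCF input") from exc

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: not a readable VCF: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF contains no samples")

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        if v.REF not in _BASES or v.ALT[0] not in _BASES:
            n_dropped += 1
            continue
        row = np.empty(len(samples), dtype=np.int8)
        for j, g in enumerate(v.genotypes):
            a, b = g[0], g[1]
            row[j] = MISSING if (a < 0 or b < 0) else a + b
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(row)
    vcf.close()

    calls = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return _finalize(
        chroms, poss, refs, alts, samples, calls, chrom_include, n_dropped, str(path)
    )


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _read_map(map_path: Path) -> list[tuple[str, str, int]]:
    """Parse a PLINK MAP file -> list of (chrom, snp_id, pos)."""
    out = []
    with _open_text(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) == 4:
                chrom, snp_id, _cm, pos = fields
            elif len(fields) == 3:
                chrom, snp_id, pos = fields
            else:
                raise FormatError(
                    f"{map_path}:{lineno}: expected 3 or 4 columns, got {len(fields)}"
                )
            try:
                out.append((chrom, snp_id, int(pos)))
            except ValueError:
                raise FormatError(
                    f"{map_path}:{lineno}: non-integer position {pos!r}"
                ) from None
    if not out:
        raise FormatError(f"{map_path}: empty MAP file")
    return out


def _code_allele_pairs(
    pairs: list[list[tuple[str, str]]], source: str
) -> tuple[np.ndarray, list[str], list[str], list[bool]]:
    """Turn per-site lists of allele pairs into alt-count codes.

    PED/TPED carry no REF/ALT semantics, so the first non-missing allele
    observed at a site is provisionally REF.  Sites with more than two
    distinct alleles are flagged for dropping.  Returns (calls, refs,
    alts, keep_flags); ``calls`` has shape (n_sites, n_samples).
    """
    n_sites = len(pairs)
    n_samples = len(pairs[0]) if n_sites else 0
    calls = np.full((n_sites, n_samples), MISSING, dtype=np.int8)
    refs: list[str] = []
    alts: list[str] = []
    keep: list[bool] = []
    for i, site_pairs in enumerate(pairs):
        alleles: list[str] = []
        for a, b in site_pairs:
            for al in (a, b):
                if al != "0" and al not in alleles:
                    alleles.append(al)
        if len(alleles) > 2:
            keep.append(False)
            refs.append("N")
            alts.append("N")
            continue
        ref = alleles[0] if alleles else "N"
        alt = alleles[1] if len(alleles) > 1 else "."
        refs.append(ref)
        alts.append(alt)
        keep.append(True)
        for j, (a, b) in enumerate(site_pairs):
            if a == "0" or b == "0":
                continue  # any partial/no call -> MISSING
            calls[i, j] = (a != ref) + (b != ref)
    return calls, refs, alts, keep


def _read_ped_map(path: Path, map_path: Path | None, chrom_include) -> GenotypeMatrix:
    path = Path(path)
    if map_path is None:
        map_path = path.with_suffix(".map")
    if not Path(map_path).exists():
        raise FileNotFoundError(f"PED+MAP input requires a MAP file; {map_path} not found")
    sites = _read_map(Path(map_path))
    n_sites = len(sites)

    samples: list[str] = []
    per_sample_pairs: list[list[tuple[str, str]]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_sites:
                raise FormatError(
                    f"{path}:{lineno}: expected {6 + 2 * n_sites} columns "
                    f"(6 + 2 x {n_sites} sites), got {len(fields)}"
                )
            samples.append(fields[1])
            geno = fields[6:]
            per_sample_pairs.append(
                [(geno[2 * k], geno[2 * k + 1]) for k in range(n_sites)]
            )
    if not samples:
        raise FormatError(f"{path}: empty PED file")

    # transpose to per-site allele pairs
    pairs = [
        [per_sample_pairs[j][i] for j in range(len(samples))] for i in range(n_sites)
    ]
    calls, refs, alts, keep = _code_allele_pairs(pairs, str(path))
    n_dropped = keep.count(False)
    keep_arr = np.asarray(keep)
    return _finalize(
        [sites[i][0] for i in range(n_sites) if keep[i]],
        [sites[i][2] for i in range(n_sites) if keep[i]],
        [refs[i] for i in range(n_sites) if keep[i]],
        [alts[i] for i in range(n_sites) if keep[i]],
        samples,
        calls[keep_arr],
        chrom_include,
        n_dropped,
        str(path),
    )


def _read_tped(path: Path, tfam_path: Path | None, chrom_include) -> GenotypeMatrix:
    path = Path(path)
    if tfam_path is None:
        candidate = path.with_suffix(".tfam")
        tfam_path = candidate if candidate.exists() else None

    chroms: list[str] = []
    poss: list[int] = []
    pairs: list[list[tuple[str, str]]] = []
    n_samples: int | None = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 6 or (len(fields) - 4) % 2:
                raise FormatError(
                    f"{path}:{lineno}: malformed TPED row ({len(fields)} columns)"
                )
            chrom, _snp_id, _cm, pos = fields[:4]
            geno = fields[4:]
            if n_samples is None:
                n_samples = len(geno) // 2
            elif len(geno) != 2 * n_samples:
                raise FormatError(
                    f"{path}:{lineno}: inconsistent sample count "
                    f"({len(geno) // 2} vs {n_samples})"
                )
            try:
                poss.append(int(pos))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer position {pos!r}"
                ) from None
            chroms.append(chrom)
            pairs.append([(geno[2 * k], geno[2 * k + 1]) for k in range(n_samples)])
    if n_samples is None:
        raise FormatError(f"{path}: empty TPED file")

    if tfam_path is not None:
        with _open_text(Path(tfam_path)) as fh:
            samples = [line.split()[1] for line in fh if line.split()]
        if len(samples) != n_samples:
            raise FormatError(
                f"{tfam_path}: {len(samples)} samples, TPED has {n_samples}"
            )
    else:
        samples = [f"S{i + 1}" for i in range(n_samples)]

    calls, refs, alts, keep = _code_allele_pairs(pairs, str(path))
    n_dropped = keep.count(False)
    keep_arr = np.asarray(keep)
    return _finalize(
        [chroms[i] for i in range(len(chroms)) if keep[i]],
        [poss[i] for i in range(len(poss)) if keep[i]],
        [refs[i] for i in range(len(refs)) if keep[i]],
        [alts[i] for i in range(len(alts)) if keep[i]],
        samples,
        calls[keep_arr],
        chrom_include,
        n_dropped,
        str(path),
    )


def read_genotypes(
    path,
    format: str = "vcf",
    *,
    map_path=None,
    tfam_path=None,
    chrom_include="autosomes",
) -> GenotypeMatrix:
    """Load multi-sample genotypes into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        Input file (the .ped file for ``ped_map``).
    format
        One of ``vcf``, ``ped_map``, ``tped``.
    map_path, tfam_path
        Companion files; default to ``path`` with the suffix swapped.
    chrom_include
        ``"autosomes"`` (default), ``None`` for all chromosomes, or an
        explicit collection of chromosome labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path, chrom_include)
    if format == "ped_map":
        return _read_ped_map(path, map_path, chrom_include)
    if format == "tped":
        return _read_tped(path, tfam_path, chrom_include)
    raise ValueError(f"unknown format {format!r}; expected vcf, ped_map or tped")


def filter_pair_sites(gm: GenotypeMatrix, a: str, b: str) -> GenotypeMatrix:
    """Restrict to sites where both ``a`` and ``b`` are called.

    Symmetric in (a, b); site order is preserved.
    """
    ga = gm.column(a)
    gb = gm.column(b)
    mask = (ga != MISSING) & (gb != MISSING)
    return gm.subset_sites(mask)


def write_calls(calls, path) -> None:
    """Write a results table: one row per (pair, metrics, call).

    ``calls`` is an iterable of ((sample1, sample2), PairMetrics,
    RelationshipCall) triples.  Tab-separated with a fixed header.
    """
    rows = []
    for (s1, s2), m, call in calls:
        rows.append(
            {
                "sample1": s1,
                "sample2": s2,
                "n_windows": m.n_windows,
                "n_high_p2": m.n_high_p2,
                "peak_flag": bool(m.peak_flag),
                "n_iw": m.n_iw,
                "frac_contig_iw": m.frac_contig_iw,
                "max_run": m.max_run,
                "predicted_label": call.label if call.label is not None else "NA",
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_calls`."""
    return pd.read_csv(path, sep="\t", dtype={"sample1": str, "sample2": str})
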