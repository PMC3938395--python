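"""Gene-dropping simulator for labeled pedigree genotype data.

Founder haplotypes are drawn site-independently from an allele
frequency spectrum (Beta(0.5, 0.5) by default, configurable);
non-founders receive one recombinant gamete from each parent, with
crossovers Poisson-distributed along each chromosome at a uniform rate
(default 1e-8 per bp per meiosis, ~1 cM/Mb, no interference).  A
symmetric per-genotype error channel perturbs called genotypes at rate
``se``.  All randomness flows from a single seed.

The simulated data emulate a WGS-scale biallelic SNV callset over the
human autosomes; site positions and frequencies (the *site panel*) can
be shared across replicate families so that individuals from different
replicates are comparable as unrelated pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .formats_io import MISSING, GenotypeMatrix
from .genomes import GRCH37_AUTOSOMES, chrom_sort_key
from .pedigree import Pedigree


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    n_sites
        Total biallelic SNV count genome-wide (the WGS condition is
        ~3.5 million sites per individual).
    chrom_lengths
        Chromosome sizes in bp (GRCh37 autosomes by default).
    beta_a, beta_b
        Shape of the Beta allele-frequency spectrum for founders.
    recomb_rate
        Expected crossovers per bp per meiosis (1e-8 ~ 1 cM/Mb).
    se
        Per-genotype error rate in [0, 0.5).
    seed
        Seeds every random draw; same seed, same output.
    """

    n_sites: int = 3_500_000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(GRCH37_AUTOSOMES)
    )
    beta_a: float = 0.5
    beta_b: float = 0.5
    recomb_rate: float = 1e-8
    se: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if not 0 <= self.se < 0.5:
            raise ValueError(f"se must be in [0, 0.5), got {self.se}")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be non-negative")


@dataclass
class SitePanel:
    """Shared site coordinates, alleles and population frequencies."""

    chrom: np.ndarray  # object, per site, sorted by (chrom, pos)
    pos: np.ndarray  # int64
    ref: np.ndarray
    alt: np.ndarray
    freq: np.ndarray  # alt-allele frequency per site
    chrom_lengths: dict[str, int]

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous per-chromosome slices of the sorted site arrays."""
        out = []
        start = 0
        for i in range(1, self.n_sites + 1):
            if i == self.n_sites or self.chrom[i] != self.chrom[start]:
                out.append((str(self.chrom[start]), slice(start, i)))
                start = i
        return out


@dataclass
class DiplotypeSet:
    """Phased 0/1 haplotypes for a set of members over one site panel."""

    panel: SitePanel
    members: list[str]
    haps: np.ndarray  # uint8, (n_members, 2, n_sites)

    def member_index(self, member: str) -> int:
        return self.members.index(member)

    def genotypes(self) -> np.ndarray:
        """True genotypes (alt-allele counts), shape (n_sites, n_members)."""
        return self.haps.sum(axis=1, dtype=np.int8).T


_ALT_OF = {"A": "G", "C": "T", "G": "A", "T": "C"}  # transitions


def make_site_panel(cfg: SimConfig, rng: np.random.Generator) -> SitePanel:
    """Place sites uniformly at random and draw their frequencies."""
    chroms = sorted(cfg.chrom_lengths, key=chrom_sort_key)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    counts = rng.multinomial(cfg.n_sites, lengths / lengths.sum())
    chrom_col: list[np.ndarray] = []
    pos_col: list[np.ndarray] = []
    for c, L, k in zip(chroms, lengths.astype(int), counts):
        pos = np.unique(rng.integers(1, L + 1, size=k))  # collisions dropped
        chrom_col.append(np.full(len(pos), c, dtype=object))
        pos_col.append(pos.astype(np.int64))
    chrom = np.concatenate(chrom_col)
    pos = np.concatenate(pos_col)
    n = len(pos)
    ref = rng.choice(np.array(list("ACGT"), dtype=object), size=n)
    alt = np.array([_ALT_OF[r] for r in ref], dtype=object)
    freq = rng.beta(cfg.beta_a, cfg.beta_b, size=n)
    return SitePanel(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        freq=freq,
        chrom_lengths=dict(cfg.chrom_lengths),
    )


def simulate_founders(
    cfg: SimConfig,
    n_founders: int,
    rng: np.random.Generator | None = None,
    *,
    panel: SitePanel | None = None,
    ids: list[str] | None = None,
) -> DiplotypeSet:
    """Draw founder haplotypes site-independently from the panel spectrum."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if panel is None:
        panel = make_site_panel(cfg, rng)
    if ids is None:
        ids = [f"F{i + 1}" for i in range(n_founders)]
    if len(ids) != n_founders:
        raise ValueError("ids length must equal n_founders")
    haps = (
        rng.random((n_founders, 2, panel.n_sites)) < panel.freq
    ).astype(np.uint8)
    return DiplotypeSet(panel=panel, members=list(ids), haps=haps)


def meiosis(
    parent_haps: np.ndarray,
    panel: SitePanel,
    recomb_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete from a (2, n_sites) parental diplotype.

    Per chromosome: crossover count ~ Poisson(length * rate) with
    uniform breakpoint positions; the gamete alternates between the
    parental haplotypes at each breakpoint, starting from one chosen
    by a fair coin.
    """
    gamete = np.empty(panel.n_sites, dtype=np.uint8)
    for chrom, sl in panel.chrom_slices():
        length = panel.chrom_lengths[chrom]
        k = rng.poisson(length * recomb_rate)
        start = int(rng.integers(2))
        if k == 0:
            gamete[sl] = parent_haps[start, sl]
            continue
        bps = np.sort(rng.integers(1, length + 1, size=k))
        src = (start + np.searchsorted(bps, panel.pos[sl], side="left")) % 2
        seg = np.where(src == 0, parent_haps[0, sl], parent_haps[1, sl])
        gamete[sl] = seg
    return gamete


def gene_drop(
    ped: Pedigree,
    founders: DiplotypeSet,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> DiplotypeSet:
    """Drop founder haplotypes down the pedigree, one meiosis per parent.

    Members are processed in topological order (parents first); the
    returned set covers every pedigree member, founders included, in
    pedigree member order.
    """
    missing = set(ped.founders) - set(founders.members)
    if missing:
        raise ValueError(f"founder haplotypes missing for {sorted(missing)}")
    panel = founders.panel
    haps_of: dict[str, np.ndarray] = {
        fid: founders.haps[founders.member_index(fid)] for fid in ped.founders
    }
    for mid in ped.topological_order:
        member = ped.members[mid]
        if member.is_founder:
            continue
        child = np.empty((2, panel.n_sites), dtype=np.uint8)
        child[0] = meiosis(haps_of[member.father], panel, cfg.recomb_rate, rng)
        child[1] = meiosis(haps_of[member.mother], panel, cfg.recomb_rate, rng)
        haps_of[mid] = child
    members = list(ped.ids)
    return DiplotypeSet(
        panel=panel,
        members=members,
        haps=np.stack([haps_of[m] for m in members]),
    )


def apply_error(
    dip: DiplotypeSet,
    se: float,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Called genotypes with a symmetric per-genotype error channel.

    With probability ``se``, independently per genotype per individual,
    the true alt-allele count is replaced by one of the two other codes
    chosen uniformly.
    """
    if not 0 <= se < 0.5:
        raise ValueError(f"se must be in [0, 0.5), got {se}")
    gt = dip.genotypes().copy()
    if se > 0:
        err = rng.random(gt.shape) < se
        n_err = int(err.sum())
        shift = rng.integers(1, 3, size=n_err).astype(np.int8)
        gt[err] = (gt[err] + shift) % 3
    panel = dip.panel
    return GenotypeMatrix(
        chrom=panel.chrom.copy(),
        pos=panel.pos.copy(),
        ref=panel.ref.copy(),
        alt=panel.alt.copy(),
        samples=list(dip.members),
        calls=gt,
    )


def simulate_family(
    ped: Pedigree,
    cfg: SimConfig,
    *,
    panel: SitePanel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[DiplotypeSet, GenotypeMatrix]:
    """Convenience: founders + gene drop + error in one call.

    Returns the true diplotypes and the error-perturbed genotype
    matrix at ``cfg.se``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    founders = simulate_founders(
        cfg, len(ped.founders), rng, panel=panel, ids=ped.founders
    )
    dip = gene_drop(ped, founders, cfg, rng)
    gm = apply_error(dip, cfg.se, rng)
    return dip, gm


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def export_vcf(gm: GenotypeMatrix, path, chrom_lengths: dict[str, int] | None = None):
    """Write a minimal VCF 4.2 with GT-only genotype columns."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=grab-simulator\n")
        if chrom_lengths:
            for c in sorted(chrom_lengths, key=chrom_sort_key):
                fh.write(f"##contig=<ID={c},length={chrom_lengths[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i in range(gm.n_sites):
            gts = "\t".join(_GT_STR[int(g)] for g in gm.calls[i])
            fh.write(
                f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{gm.alt[i]}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def export_ped_map(gm: GenotypeMatrix, prefix, family_id: str = "FAM1"):
    """Write PLINK PED+MAP text files (<prefix>.ped / <prefix>.map)."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for i in range(gm.n_sites):
            fh.write(f"{gm.chrom[i]}\tsnp{i + 1}\t0\t{gm.pos[i]}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for j, sample in enumerate(gm.samples):
            fields = [family_id, sample, "0", "0", "0", "0"]
            col = gm.calls[:, j]
            for i in range(gm.n_sites):
                g = col[i]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [gm.ref[i], gm.ref[i]]
                elif g == 1:
                    fields += [gm.ref[i], gm.alt[i]]
                else:
                    fields += [gm.alt[i], gm.alt[i]]
            fh.write(" ".join(fields) + "\n")


def write_truth_table(ped: Pedigree, path, include_self: bool = False) -> None:
    """TSV of every sample pair with its true relationship label."""
    with open(path, "w") as fh:
        fh.write("sample1\tsample2\ttrue_label\n")
        for a, b, label in ped.pair_labels(include_self=include_self):
            fh.write(f"{a}\t{b}\t{label}\n")


def read_truth_table(path) -> list[tuple[str, str, str]]:
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines()):
        if lineno == 0 and line.startswith("sample1"):
            continue
        if not line.strip():
            continue
        a, b, label = line.split("\t")
        out.append((a, b, label))
    return out


def thin_to_array_density(
    gm: GenotypeMatrix, n_sites: int, rng: np.random.Generator
) -> GenotypeMatrix:
    """Down-sample sites uniformly, emulating a genotyping-array panel
    (~0.8M sites for the classic high-density arrays)."""
    if n_sites >= gm.n_sites:
        return gm
    keep = np.sort(rng.choice(gm.n_sites, size=n_sites, replace=False))
    return gm.subset_sites(keep)
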