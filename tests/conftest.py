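import numpy as np
import pytest

from grab import SimConfig, default_family_pedigree
from grab.simulate import gene_drop, make_site_panel, simulate_founders

# small genome used across integration tests: 8 x 60 Mb autosomes
SMALL_LENGTHS = {str(i): 60_000_000 for i in range(1, 9)}
SMALL_SITES = 120_000
SMALL_SEED = 20140228


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        n_sites=SMALL_SITES, chrom_lengths=dict(SMALL_LENGTHS), seed=SMALL_SEED
    )


@pytest.fixture(scope="session")
def small_family(small_cfg):
    """One simulated 26-member family on the small genome (true diplotypes)."""
    ped = default_family_pedigree()
    rng = np.random.default_rng(SMALL_SEED)
    panel = make_site_panel(small_cfg, rng)
    founders = simulate_founders(
        small_cfg, len(ped.founders), rng, panel=panel, ids=ped.founders
    )
    dip = gene_drop(ped, founders, small_cfg, rng)
    return ped, dip


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")


@pytest.fixture
def tiny_vcf(tmp_path):
    """3 samples, 5 records, one multi-allelic (dropped on read)."""
    path = tmp_path / "tiny.vcf"
    write_lines(
        path,
        [
            "##fileformat=VCFv4.2",
            "##contig=<ID=1,length=2000000>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNA1\tNA2\tNA3",
            "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1",
            "1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/1\t./.",
            "1\t300\t.\tG\tA,C\t.\tPASS\t.\tGT\t0/1\t0/2\t1/1",
            "1\t400\t.\tT\tC\t.\tPASS\t.\tGT\t0|1\t1|1\t0/0",
            "1\t500\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0",
        ],
    )
    return path


@pytest.fixture
def tiny_tped(tmp_path):
    """TPED/TFAM equivalent of tiny_vcf minus the multi-allelic record.

    First-observed allele per site matches the VCF REF so the codes
    agree between the two readers.
    """
    tped = tmp_path / "tiny.tped"
    tfam = tmp_path / "tiny.tfam"
    write_lines(
        tped,
        [
            "1 snp1 0 100 A A A G G G",
            "1 snp2 0 200 C T C T 0 0",
            "1 snp3 0 400 T C C C T T",
            "1 snp4 0 500 A A A A A A",
        ],
    )
    write_lines(
        tfam,
        [
            "FAM NA1 0 0 0 0",
            "FAM NA2 0 0 0 0",
            "FAM NA3 0 0 0 0",
        ],
    )
    return tped
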