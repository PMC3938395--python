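"""Reference chromosome lengths used for windowing and simulation.

Only the 22 human autosomes are listed: identity-by-state expectations
differ on the sex chromosomes (hemizygosity in males), so the pipeline
restricts itself to autosomes by default.
"""

from __future__ import annotations

# GRCh37 / hg19 autosome lengths in bp.
GRCH37_AUTOSOMES: dict[str, int] = {
    "1": 249250621,
    "2": 243199373,
    "3": 198022430,
    "4": 191154276,
    "5": 180915260,
    "6": 171115067,
    "7": 159138663,
    "8": 146364022,
    "9": 141213431,
    "10": 135534747,
    "11": 135006516,
    "12": 133851895,
    "13": 115169878,
    "14": 107349540,
    "15": 102531392,
    "16": 90354753,
    "17": 81195210,
    "18": 78077248,
    "19": 59128983,
    "20": 63025520,
    "21": 48129895,
    "22": 51304566,
}


def chrom_sort_key(label: str) -> tuple[int, int | str]:
    """Sort key giving the natural chromosome order 1..22, X, Y, MT, other.

    Accepts labels with or without a ``chr`` prefix.
    """
    name = label[3:] if label.lower().startswith("chr") else label
    if name.isdigit():
        return (0, int(name))
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if name.upper() in special:
        return (0, special[name.upper()])
    return (1, name)


def is_autosome(label: str) -> bool:
    name = label[3:] if label.lower().startswith("chr") else label
    return name.isdigit() and 1 <= int(name) <= 22
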