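"""Regenerate the packaged default decision-tree thresholds.

Calibrates on a single seed-fixed simulated family at the desk-scale
WGS study condition (SE=0) and writes the versioned config file that
`grab.classifier.default_thresholds()` loads.

Usage:  python scripts/build_default_thresholds.py
"""

from pathlib import Path

from grab.experiments import run_relationship_study

SEED = 20140228

out = Path(__file__).resolve().parents[1] / "src" / "grab" / "data" / "default_thresholds.txt"
out.parent.mkdir(parents=True, exist_ok=True)

result = run_relationship_study(
    SEED, se=0.0, n_families=1, eval_labels=(), n_unrelated_pairs=0
)
result.thresholds.save(out)
print(f"wrote {out}")
print(result.thresholds)
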