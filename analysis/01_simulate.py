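"""Generate the study's synthetic fixtures.

Writes paired neutral + gradient OTU tables, metadata, phylogeny and
ground-truth JSON at two scales: a seconds-scale "tiny" fixture
(50 OTUs x 12 samples, depth 1,000) and a full-scale one emulating a
rarefied soil-microcosm survey (2,000 OTUs x 30 samples = 5 doses x 6
replicates, depth 39,134 reads).  Raw fixture files go to scratch/
(they are inputs regenerable from a seed, not results); a small summary
lands in results/.
"""

import json
from pathlib import Path

from assemblage.core_io import read_otu_table
from assemblage.synthetic_data import make_fixtures

ROOT = Path(__file__).resolve().parents[1]
SEED = 42


def main() -> None:
    out_dir = ROOT / "scratch" / "fixtures"
    written = make_fixtures(out_dir, seed=SEED)
    summary = {}
    for scale, paths in written.items():
        table = read_otu_table(paths["gradient_table"])
        summary[scale] = {
            "n_samples": table.n_samples,
            "n_otus": table.n_otus,
            "depth": int(table.counts.sum(axis=1)[0]),
            "files": paths,
        }
        print(f"{scale}: {table.n_samples} samples x {table.n_otus} OTUs, "
              f"depth {summary[scale]['depth']}")
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "01_fixtures_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    print(f"fixtures under {out_dir}")


if __name__ == "__main__":
    main()
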