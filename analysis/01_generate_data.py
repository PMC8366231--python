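"""Generate the synthetic study inputs and write them to disk.

Produces the lexicon (TSV), the lexome vector store (TSV), the segment
mean-duration table (TSV) and a ground-truth dump of the generating
configuration, under results/data/.
"""

from __future__ import annotations

import argparse
import dataclasses
import json
from pathlib import Path

import pandas as pd

from ldldur.lexicon import write_lexicon
from ldldur.synthetic import (
    GeneratorConfig,
    generate_lexicon,
    generate_segment_table,
    generate_vector_store,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out-dir", type=Path, default=Path("results/data"))
    args = parser.parse_args()

    config = GeneratorConfig(seed=args.seed)
    lexicon, inventory = generate_lexicon(config)
    store = generate_vector_store(lexicon, config)
    segments = generate_segment_table(config)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    write_lexicon(lexicon, args.out_dir / "lexicon.tsv")
    store.write(args.out_dir / "lexome_vectors.tsv")
    pd.Series(segments, name="mean_duration_ms").rename_axis("phone").to_csv(
        args.out_dir / "segment_durations.tsv", sep="\t"
    )
    truth = dataclasses.asdict(config)
    truth["inventory"] = {"symbols": list(inventory.symbols)}
    (args.out_dir / "generator_config.json").write_text(
        json.dumps(truth, default=str, indent=2) + "\n"
    )

    n_derived = sum(e.is_derived for e in lexicon)
    print(f"lexicon: {len(lexicon)} word types ({n_derived} derived, "
          f"{len(lexicon) - n_derived} monomorphemic)")
    print(f"vector store: {len(store.vectors)} lexomes in {store.dimension} dimensions")
    print(f"segment table: {len(segments)} phones")
    print(f"written to {args.out_dir}/")


if __name__ == "__main__":
    main()
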