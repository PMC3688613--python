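"""Simulate the study stand: two hybridizing species in a ~5 ha plot.

Generates the default synthetic scenario (298 adults at unequal species
abundance, 12 SSR-like loci, 51 mothers sampled for ~60 open-pollinated
offspring each, 45% pollen immigration) and writes the raw tables that
every later step consumes.
"""

from pathlib import Path

import numpy as np

from matenet import io as mio
from matenet.io import PipelineConfig
from matenet.pipeline import simulate_stage, stage_seeds

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig()
    seeds = stage_seeds(config.seed)
    stand, offspring, refs = simulate_stage(config, seeds)

    config.to_yaml(OUT / "config.yaml")
    mio.write_genotypes(stand.ids, stand.genotypes, OUT / "genotypes.csv")
    mio.write_coordinates(stand.coords_frame(), OUT / "coordinates.csv")
    mio.write_pedigree(offspring, OUT / "pedigree.csv")
    mio.write_genotypes([o.offspring_id for o in offspring],
                        np.stack([o.genotype for o in offspring]),
                        OUT / "offspring_genotypes.csv")
    mio.write_assignments(refs, OUT / "reference_assignments.csv")

    n_ext = sum(o.true_father_id == "EXTERNAL" for o in offspring)
    print(f"stand: {stand.n_adults} adults "
          f"({(stand.species == 'A').sum()} A / {(stand.species == 'B').sum()} B) "
          f"on {stand.extent[0]:.0f} x {stand.extent[1]:.0f} m")
    print(f"progeny: {len(offspring)} offspring from {config.n_mothers} mothers; "
          f"{n_ext} externally sired ({n_ext / len(offspring):.0%})")
    print(f"reference labels: genotype {refs['genotype'].value_counts().to_dict()}, "
          f"morphology {refs['morphology'].value_counts().to_dict()}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
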