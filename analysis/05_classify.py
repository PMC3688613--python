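"""Classify adults into two species plus intermediates.

Applies the triangular rule to the three-EHN fits: an individual is a
pure species when its node lies on the edge between the unconnected
EHN 0 and one species EHN; nodes inside the triangle (mixing both
species EHNs) are reproductive / pedigree intermediates.
"""

from pathlib import Path

from matenet import classify
from matenet import io as mio
from matenet.io import PipelineConfig

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    config = PipelineConfig.from_yaml(OUT / "config.yaml")
    for name, criterion in (("mating", "interfertility"), ("relatedness", "relatedness")):
        fit = mio.read_fit(OUT / f"{name}_fit.json")
        labels = classify.classify_memberships(fit, epsilon=config.epsilon,
                                               criterion=criterion)
        mio.write_assignments(labels, OUT / f"assignments_{criterion}.csv")
        coords = classify.ternary_coordinates(fit)
        coords.reset_index().to_csv(OUT / f"ternary_{criterion}.csv", index=False)
        counts = labels["label"].value_counts().to_dict()
        low = int(labels["low_information"].sum())
        print(f"{criterion}: {counts} ({low} low-information nodes)")


if __name__ == "__main__":
    main()
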