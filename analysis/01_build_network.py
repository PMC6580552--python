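"""Build and validate the synthetic genome-scale pathway network.

Generates the study network (3755 components, 4750 reactions, 30 overlapping
pathways), checks every structural invariant, and writes a summary table of
pathway sizes.  The full model JSON goes to scratch/ for the later stages.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import MODEL_JSON, RESULTS, SCRATCH, STUDY_SPEC

from metscreen.network import model_summary, save_model, validate_model
from metscreen.synth import generate_network


def main():
    model = generate_network(STUDY_SPEC)
    violations = validate_model(model)
    print(f"network: {len(model.components)} components, {len(model.reactions)} reactions, "
          f"{len(model.pathways)} pathways; {len(violations)} invariant violations")
    assert not violations

    summary = model_summary(model)
    out = RESULTS / "01_network"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        sorted(summary.pathway_sizes.items()), columns=["pathway", "n_components"]
    ).to_csv(out / "pathway_sizes.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "n_components": summary.n_components,
        "n_reactions": summary.n_reactions,
        "n_pathways": summary.n_pathways,
        **{f"n_{k}": v for k, v in sorted(summary.n_components_by_kind.items())},
    }]).to_csv(out / "model_summary.tsv", sep="\t", index=False)

    SCRATCH.mkdir(parents=True, exist_ok=True)
    save_model(model, MODEL_JSON)
    print(f"kind breakdown: {summary.n_components_by_kind}")
    print(f"wrote {out / 'model_summary.tsv'} and model JSON to scratch/")


if __name__ == "__main__":
    main()
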