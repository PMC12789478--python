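#!/usr/bin/env python
"""Parameter-recovery experiment for the Powell calibration pipeline.

Generates noisy synthetic monoculture datasets (5% cell CV, 3
replicates) from the packaged truth, refits from perturbed starting
points, and tabulates per-parameter relative errors.  Parameters whose
+/-50% perturbation barely changes the loss are flagged
non-identifiable and excluded from the recovery summary -- with the
batch design used here that is typically the Monod K_M of the primary
substrate, which the data only constrain near depletion.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import gutswitch as gs

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    model = gs.build_default_community()
    report, flags, summary = gs.recovery_experiment(
        model, noise_level=0.05, n_replicates=3, seeds=(1, 2, 3, 4, 5))
    report.to_csv(OUT / "recovery.csv", index=False)
    print("identifiability flags:")
    for p, ident in flags.items():
        print(f"  {p}: {'identifiable' if ident else 'NON-identifiable'}")
    print(f"seeds with all identifiable parameters within 20%: "
          f"{summary['seeds_recovered']}/{summary['n_seeds']}")
    print(f"median relative error (identifiable): "
          f"{100 * summary['median_rel_error']:.2f}%")
    print(f"wrote {OUT / 'recovery.csv'}")


if __name__ == "__main__":
    main()
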