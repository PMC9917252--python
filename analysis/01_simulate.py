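"""Simulate dSTORM measurements for the two fixation-like conditions.

Writes three synthetic fields per group (HPF/FS-like and PFA-like):
a rapidSTORM-dialect localization table, an 8-bit bouton mask and a
ground-truth sidecar per field, under scratch/data/.
"""

from pathlib import Path

from aznano import locio, synthgen

OUT = Path(__file__).resolve().parent.parent / "scratch" / "data"
GROUPS = {"hpf": synthgen.SyntheticParams.paper_hpf, "pfa": synthgen.SyntheticParams.paper_pfa}
SEEDS = (101, 102, 103)


def main() -> None:
    for group, maker in GROUPS.items():
        for seed in SEEDS:
            params = maker(seed=seed)
            table, mask, truth = synthgen.generate_field(params)
            d = OUT / f"{group}_{seed}"
            d.mkdir(parents=True, exist_ok=True)
            locio.write_localizations(table, d / "localizations.txt")
            locio.write_mask_image(mask, d / "mask.tif")
            synthgen.write_ground_truth(truth, d / "ground_truth.txt")
            print(
                f"{group} seed {seed}: {len(table)} localizations, "
                f"{len(truth.az_centers)} AZs, background "
                f"{truth.background_density:.0f}/um2"
            )


if __name__ == "__main__":
    main()
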