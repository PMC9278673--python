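"""Build the reference picket-fence plans and the fault-injection manifest.

Writes the two reference plans (YAML) and the 110-scenario manifest with
per-scenario ground truth to results/.
"""

from pathlib import Path

from pfqa.errors import enumerate_matrix, scenario_manifest
from pfqa.mlc import build_mlc_model, build_reference_plan, write_plan

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    for name in ("M120", "HD120"):
        plan = build_reference_plan(build_mlc_model(name))
        write_plan(plan, RESULTS / f"{name.lower()}_reference_plan.yaml")
        print(
            f"{name}: 10 slits of {plan.nominal_gap} mm gap spaced 15 mm, "
            f"X1/X2 = {plan.jaw_x1:.0f}/{plan.jaw_x2:.0f} mm, "
            f"Y aperture = {2 * plan.jaw_y:.0f} mm, {plan.mu:.0f} MU"
        )
    scenarios = enumerate_matrix()
    manifest = scenario_manifest(scenarios)
    manifest.to_csv(RESULTS / "scenario_manifest.csv", index=False)
    counts = manifest.groupby(["mlc", "category"]).size().unstack(fill_value=0)
    print(f"\n{len(scenarios)} scenarios ({len(scenarios) // 2} per MLC):")
    print(counts.to_string())


if __name__ == "__main__":
    main()
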