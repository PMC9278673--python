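"""Width-measurement blind spots of the two threshold strategies.

Renders noiseless images with the slits opened uniformly or one slit
opened alone, and tabulates the width change reported by the per-slit
(local) and image-wide (global) threshold strategies plus the slit-signal
response.  Finding: the global threshold cancels uniform openings almost
exactly but reacts strongly on *unopened* slits when a single slit pulls
the shared threshold up; the local threshold under-reports every opening
(< half the injected value) while the slit integral tracks it linearly.
"""

from pathlib import Path

import pandas as pd

from pfqa.analyze import analyze_image, relative_global_config, relative_local_config
from pfqa.errors import ErrorSpec, apply_error
from pfqa.mlc import build_mlc_model, build_reference_plan
from pfqa.simulate import BeamModel, ImagerSpec, render_image

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    mlc = build_mlc_model("M120")
    plan = build_reference_plan(mlc)
    imager, beam = ImagerSpec(), BeamModel()
    ref_img = render_image(plan, imager, beam, noise=False)
    configs = {"local": relative_local_config(), "global": relative_global_config()}
    refs = {k: analyze_image(ref_img, plan, mlc, c) for k, c in configs.items()}

    rows = []
    for target, label in (("all", "all slits"), ((2,), "slit 2 only")):
        for d in (0.1, 0.2, 0.3, 0.4, 0.5):
            opened = apply_error(
                plan, ErrorSpec("global_width", d, target_slits=target, bank="A")
            )
            img = render_image(opened, imager, beam, noise=False)
            row = {"opening_mm": d, "target": label}
            for k, cfg in configs.items():
                res = analyze_image(img, plan, mlc, cfg, baseline=refs[k])
                on_target = [
                    v for (s, b), v in res.relative.width_error.items()
                    if target == "all" or s in target
                ]
                off_target = [
                    v for (s, b), v in res.relative.width_error.items()
                    if target != "all" and s not in target
                ]
                row[f"{k}_dw_target_mm"] = round(max(on_target, key=abs), 4)
                row[f"{k}_dw_others_mm"] = (
                    round(max(off_target, key=abs), 4) if off_target else 0.0
                )
            res_sig = analyze_image(img, plan, mlc, configs["local"], baseline=refs["local"])
            sig0 = refs["local"].relative.signal
            rel = max(
                res_sig.relative.signal[s] / sig0[s] - 1.0 for s in sig0
            )
            row["signal_rel_change"] = round(rel, 4)
            rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "width_response.csv", index=False)
    print(df.to_string(index=False))
    uniform = df[df.target == "all slits"]
    print(
        f"\nuniform opening: |global-threshold width change| <= "
        f"{uniform.global_dw_target_mm.abs().max():.3f} mm while the slit signal "
        f"rises up to {uniform.signal_rel_change.max():.0%}"
    )


if __name__ == "__main__":
    main()
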