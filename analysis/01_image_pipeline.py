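"""Exercise the image pipeline end to end on three synthetic eyes.

Generates a noise-free clean eye, a noisy eye with vessels and lesions,
and a DME eye; quantifies each with the ETDRS site-based measurement;
and tabulates measured vs programmed sector values.  Images and masks go
to scratch/ (regenerable); the comparison table to results/.
"""

from pathlib import Path

import pandas as pd

from colorfaf import imaging_io as io
from colorfaf.etdrs_grid import measure_eye
from colorfaf.imaging_io import SECTORS
from colorfaf.synthetic_data import ImageSimConfig, VesselSpec, generate_eye_image

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "images"
RESULTS = ROOT / "results"


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    configs = {
        "clean": ImageSimConfig(
            shape=(700, 700), um_per_pixel=10.0, eye_id="clean",
            noise_sd=0.0, vessels=VesselSpec(count=0), lesions=(),
            sector_gefc={s: float(17 + 3 * i) for i, s in enumerate(SECTORS)},
            sector_refc={s: float(26 + 2 * i) for i, s in enumerate(SECTORS)},
        ),
        "dr_noisy": ImageSimConfig(shape=(700, 700), um_per_pixel=10.0, eye_id="dr_noisy"),
        "dme": ImageSimConfig(shape=(700, 700), um_per_pixel=10.0, eye_id="dme", dme=True),
    }
    rows = []
    for name, cfg in configs.items():
        image, mask, truth = generate_eye_image(cfg, seed=7)
        io.write_image(image, SCRATCH / f"{name}.png")
        io.write_mask(mask, SCRATCH / f"{name}_mask.png")
        io.write_metadata(image.metadata, SCRATCH / f"{name}.json")
        measured = measure_eye(image, mask, radius_um=100)
        for s in SECTORS:
            m = measured.get(s)
            rows.append(
                {
                    "eye": name, "sector": s,
                    "gefc_true": truth["sectors"][s]["gefc"],
                    "gefc_measured": m.gefc_mean if m else float("nan"),
                    "refc_true": truth["sectors"][s]["refc"],
                    "refc_measured": m.refc_mean if m else float("nan"),
                    "n_pixels": m.n_pixels if m else 0,
                }
            )
    table = pd.DataFrame(rows)
    table["gefc_err"] = (table.gefc_measured - table.gefc_true).abs()
    table["refc_err"] = (table.refc_measured - table.refc_true).abs()
    table.to_csv(RESULTS / "image_recovery.csv", index=False, float_format="%.3f")
    clean_exact = (table.loc[table.eye == "clean", ["gefc_err", "refc_err"]] == 0).all().all()
    print(f"quantified {len(configs)} synthetic eyes ({len(table)} sector measurements)")
    print(f"noise-free eye recovered exactly: {clean_exact}")
    print("worst-case absolute error by eye (GEFC / REFC):")
    for name, sub in table.groupby("eye"):
        print(f"  {name:9s} {sub.gefc_err.max():6.3f} / {sub.refc_err.max():6.3f}")
    print(f"wrote {RESULTS / 'image_recovery.csv'}")


if __name__ == "__main__":
    main()
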