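"""Image-stack preprocessing demonstration: render a synthetic camera
stack for one IR700 condition (with 8% photobleaching drift and a static
background), run the background/bleach/ROI reduction, and compare the
recovered TRAST curve to the generating model curve. Also calibrates the
beam profile from a reference-dye image.

Writes results/preprocessing_check.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from trastkit.preprocessing import (fit_gaussian_waist, irradiance_map,
                                    stack_to_trast_curve)
from trastkit.synthetic import (NoiseModel, StackGeometry,
                                gaussian_reference_image, make_design,
                                simulate_image_stack)

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    design = make_design("IR700_IRRADIANCE")
    cond = design.conditions[2]
    geom = StackGeometry()

    noise = NoiseModel(mult_sigma=0.0, bleach_amplitude=0.08)
    stack, truth_curve = simulate_image_stack(cond, design.truth, noise,
                                              seed=1, geom=geom)
    ref_img = gaussian_reference_image(geom)
    irr = irradiance_map(ref_img * 1000.0, total_power_W=1e-3,
                         pixel_size_um=geom.pixel_size_um)
    curve = stack_to_trast_curve(stack, irr, roi_radius_um=geom.roi_radius_um)

    rel_err = np.abs(curve.value - truth_curve.value) / truth_curve.value
    waist, _ = fit_gaussian_waist(irr)

    pd.DataFrame({"w_s": curve.w_s, "F_norm_recovered": curve.value,
                  "F_norm_model": truth_curve.value,
                  "rel_error": rel_err}).to_csv(
        OUT / "preprocessing_check.csv", index=False)

    print(f"stack: {stack.frames.shape[0]} frames + "
          f"{stack.reference_frames.shape[0]} reference frames, "
          f"{stack.frames.shape[1]}x{stack.frames.shape[2]} px")
    print(f"injected bleaching: 8%; residual error after correction: "
          f"max {rel_err.max():.2e} (relative)")
    print(f"calibrated 1/e2 beam radius: {waist:.2f} um "
          f"(generator: {geom.waist_um} um)")
    print(f"ROI-mean irradiance attached: "
          f"{curve.meta['irradiance_W_cm2']:.3g} W/cm2")


if __name__ == "__main__":
    main()
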