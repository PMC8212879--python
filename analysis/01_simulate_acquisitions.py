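#!/usr/bin/env python
"""Generate one example of each synthetic acquisition and write it to disk.

Produces a P-SHG sweep, an analyzed channel pair, an LHCP/RHCP chiral pair, an
attenuated z-series and a fiber phantom (TIFF + sidecar under scratch/, since
images are bulky), plus a ground-truth manifest under results/analysis/.
"""

import json
from pathlib import Path

import numpy as np
import tifffile

from shgmetrics.io import write_stack
from shgmetrics.synth import (SyntheticScene, gen_chiral_pair, gen_depth_series,
                              gen_fiber_phantom, gen_polarimetric_channels,
                              gen_pshg_stack)

IMG_DIR = Path("scratch/example_acquisitions")
OUT_DIR = Path("results/analysis")


def main():
    IMG_DIR.mkdir(parents=True, exist_ok=True)
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    manifest = {}

    scene = SyntheticScene(b_true=2.0, phi_deg=30.0, amplitude=250.0,
                           shape=(64, 64), noise="poisson", seed=101)
    write_stack(gen_pshg_stack(scene), IMG_DIR / "pshg.tif", IMG_DIR / "pshg.yml")
    manifest["pshg"] = {"b_true": 2.0, "phi_deg": 30.0, "peak_counts": 1000}

    par, perp = gen_polarimetric_channels(
        SyntheticScene(beta_true=0.7, b_true=2.0, amplitude=250.0,
                       shape=(64, 64), noise="poisson", seed=102))
    write_stack(par, IMG_DIR / "par.tif", IMG_DIR / "par.yml")
    write_stack(perp, IMG_DIR / "perp.tif", IMG_DIR / "perp.yml")
    manifest["channels"] = {"beta_true": 0.7}

    pair = gen_chiral_pair(SyntheticScene(cd_epsilon=0.4, amplitude=1000.0,
                                          shape=(64, 64), noise="poisson",
                                          seed=103))
    write_stack(pair, IMG_DIR / "chiral.tif", IMG_DIR / "chiral.yml")
    manifest["chiral"] = {"cd_epsilon": 0.4}

    series = gen_depth_series(SyntheticScene(mu_atten_per_um=0.01,
                                             amplitude=500.0, shape=(64, 64),
                                             noise="poisson", seed=104),
                              n_sections=9, z_step_um=10.0)
    write_stack(series, IMG_DIR / "depth.tif", IMG_DIR / "depth.yml")
    manifest["depth"] = {"mu_atten_per_um": 0.01, "n_sections": 9}

    phantom, truth = gen_fiber_phantom(SyntheticScene(
        fiber_spec=[(50.0, 2.0, 1.0, 20.0), (50.0, 2.0, 2 / np.pi, 80.0)],
        shape=(160, 160), pixel_size_um=0.5, amplitude=1000.0, seed=105))
    tifffile.imwrite(IMG_DIR / "fibers.tif", phantom.astype(np.float32))
    manifest["fibers"] = [{k: v for k, v in t.items() if k != "centerline_px"}
                          for t in truth]

    (OUT_DIR / "simulated_manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n")
    print(f"wrote example acquisitions to {IMG_DIR}/ "
          f"and ground truth to {OUT_DIR}/simulated_manifest.json")


if __name__ == "__main__":
    main()
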