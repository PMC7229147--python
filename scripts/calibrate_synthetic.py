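"""One-off pilot calibration of the paper-like synthetic dataset.

Measures the expected section entropy S as a function of the planted
proliferating-cell count N by running the full render -> Otsu -> S pipeline
over pilot seeds, then solves for the per-series cell counts that plant the
target joint/phalanx ratios (~5x moorhen-like, ~2x grebe-like, ~0.95
coot-like). Writes src/webfoot/calibration.json.

Run from the repository root:  python scripts/calibrate_synthetic.py
"""

import json
from pathlib import Path

import numpy as np

from webfoot.entropy import measure_section
from webfoot.synth import RenderSpec, generate_point_pattern, render_section

REGION = (40, 340)  # px; tall thin section so typical pair distances exceed W_max
IMAGE = (512, 512)
RENDER = {"sigma": 1.5}
PILOT_SEEDS = range(1000, 1005)
PROBE_N = list(range(60, 301, 20))

# phalanx-side cell counts chosen a priori (grebe > moorhen: the grebe-like
# series carries higher entropy overall); joint side solved from the target ratio
PHALANX_N = {"moorhen_like": 80, "grebe_like": 110, "coot_like": 110}
TARGET_RATIO = {"moorhen_like": 5.0, "grebe_like": 2.0, "coot_like": 0.95}


def mean_S(n: int) -> float:
    vals = []
    for i, seed in enumerate(PILOT_SEEDS):
        pat = generate_point_pattern("poisson", n, REGION, seed=seed * 17 + n)
        spec = RenderSpec(shape=IMAGE, seed=seed * 31 + n + 1, **RENDER)
        nuc, pro, _ = render_section(pat, spec)
        vals.append(measure_section(nuc, pro, "pilot", "1", "joint", i + 1).S)
    return float(np.mean(vals))


def main() -> None:
    curve = {n: mean_S(n) for n in PROBE_N}
    ns = np.array(sorted(curve))
    ss = np.array([curve[n] for n in ns])
    print("pilot S(N):")
    for n, s in zip(ns, ss):
        print(f"  N={n:4d}  S={s:12.0f}")

    series = {}
    achieved = {}
    for name, n_ph in PHALANX_N.items():
        s_ph = float(np.interp(n_ph, ns, ss))
        s_target = TARGET_RATIO[name] * s_ph
        n_joint = int(round(np.interp(s_target, ss, ns)))
        series[name] = {"joint": n_joint, "phalanx": n_ph}
        achieved[name] = float(np.interp(n_joint, ns, ss)) / s_ph
        print(f"{name}: phalanx N={n_ph} (S~{s_ph:.0f}) -> joint N={n_joint} "
              f"(pilot ratio {achieved[name]:.2f}, target {TARGET_RATIO[name]})")

    out = {
        "region": {"width": REGION[0], "height": REGION[1]},
        "image": list(IMAGE),
        "render": RENDER,
        "series": series,
        "targets": TARGET_RATIO,
        "pilot": {
            "seeds": [int(s) for s in PILOT_SEEDS],
            "probe_n": [int(n) for n in ns],
            "mean_S": [round(float(s), 1) for s in ss],
            "achieved_ratio": {k: round(v, 3) for k, v in achieved.items()},
        },
    }
    path = Path(__file__).resolve().parent.parent / "src" / "webfoot" / "calibration.json"
    path.write_text(json.dumps(out, indent=2) + "\n")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
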