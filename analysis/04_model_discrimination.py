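"""Model discrimination under ParB-amount variation.

Three competing pictures predict different responses of the binding
profile when the cellular ParB amount m changes:

* caging with fixed cluster size — profiles overlap after amplitude
  rescaling (shape set by geometry alone);
* caging with constant cluster concentration (sigma ~ m^(1/3)) — shapes
  change with m;
* spreading-and-bridging — triangles of slope 1/m, shapes change with m;
* 1-D filament — sharp drop to an m-proportional plateau, shapes change.

For each family the profiles are least-squares rescaled onto the largest-m
member and the residual shape deviation is recorded; only the fixed-size
caging family collapses. Writes results/model_discrimination.json.
"""

import json
from pathlib import Path

import numpy as np

from parbcage import (
    F_PLASMID,
    ScenarioSpec,
    one_d_spreading_profile,
    rescale_overlap,
    scenario_family,
    spreading_bridging_profile,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

RATIOS = (0.4, 1.0, 16.0, 28.0)
WINDOW = (0.0, 10_000.0)


def max_shape_deviation(profiles) -> float:
    """Max |c·profile − reference| over the window after least-squares
    amplitude rescaling onto the last (largest-m) profile."""
    ref = profiles[-1]
    worst = 0.0
    for prof in profiles[:-1]:
        c = rescale_overlap(prof, ref, WINDOW)
        sel = (prof.offsets_bp >= WINDOW[0]) & (prof.offsets_bp <= WINDOW[1])
        dev = np.max(np.abs(c * prof.density[sel] - ref.density[sel]))
        worst = max(worst, float(dev))
    return worst


def main() -> None:
    p = F_PLASMID
    x = np.arange(0.0, p.enriched_length_bp + 1.0, 10.0)
    m_ref = 360.0

    families = {
        "caging_constant_size": scenario_family(
            ScenarioSpec("constant_size", m_ref, RATIOS), p, x
        ),
        "caging_constant_concentration": scenario_family(
            ScenarioSpec("constant_concentration", m_ref, RATIOS), p, x
        ),
        "spreading_bridging": [
            spreading_bridging_profile(m_ref * r, x) for r in RATIOS
        ],
        "one_d_filament": [
            one_d_spreading_profile(m_ref * r, 2e-5, x) for r in RATIOS
        ],
    }
    out = {name: max_shape_deviation(profs) for name, profs in families.items()}
    (RESULTS / "model_discrimination.json").write_text(json.dumps(out, indent=2) + "\n")

    print(f"Max shape deviation after amplitude rescaling (ParB ratios {RATIOS}):")
    for name, dev in out.items():
        verdict = "collapses" if dev < 1e-9 else "does not collapse"
        print(f"  {name:32s} {dev:.3e}  ({verdict})")
    print("Only the fixed-cluster-size caging family is amount-invariant, "
          "matching the observed ~70-fold-range invariance of the ChIP profile.")


if __name__ == "__main__":
    main()
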