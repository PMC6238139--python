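"""Closed-form occupancy law and its physical normalization.

Evaluates the nucleation-and-caging density for the F-plasmid parameter
set, ties the amplitude κ to the total cluster-bound ParB count N_t over
the one-sided 15-Kbp enriched length, and converts the two reported fit
slopes A1 into Kuhn lengths. Writes results/closed_form.json and the
occupancy curve as results/occupancy_f_plasmid.tsv.
"""

import json
from pathlib import Path

import numpy as np

from parbcage import (
    F_PLASMID,
    BindingProfile,
    kappa_from_total,
    nc_density,
    total_from_kappa,
    write_profile_tsv,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    p = F_PLASMID
    n_total = total_from_kappa(p.kappa, p)
    kappa_back = kappa_from_total(n_total, p)

    # Kuhn length from the fitted decay slope A1 = a/3sigma^2 (per nm)
    kuhn_from_a1 = {}
    for label, a1 in (("f_plasmid", 1.96e-4), ("chromosome", 4.33e-4)):
        a_nm = 3.0 * p.sigma_nm**2 * a1
        kuhn_from_a1[label] = {"A1_per_nm": a1, "kuhn_nm": a_nm, "kuhn_bp": a_nm / p.nm_per_bp}

    s = np.arange(0.0, p.enriched_length_bp + 1.0, 10.0)
    write_profile_tsv(BindingProfile(s, nc_density(s, p)), RESULTS / "occupancy_f_plasmid.tsv")

    out = {
        "kappa": p.kappa,
        "n_total_one_sided_15kbp": n_total,
        "n_total_rounded_to_ten": int(round(n_total / 10.0) * 10),
        "kappa_roundtrip": kappa_back,
        "kuhn_length_from_A1": kuhn_from_a1,
        "density_at_parS": nc_density(0.0, p),
    }
    (RESULTS / "closed_form.json").write_text(json.dumps(out, indent=2) + "\n")

    print(f"kappa = {p.kappa} over a one-sided {p.enriched_length_bp/1000:.0f}-Kbp "
          f"enriched length gives N_t = {n_total:.1f} (~{out['n_total_rounded_to_ten']}).")
    print(f"Inverse check: N_t = {n_total:.1f} maps back to kappa = {kappa_back:.4f}.")
    for label, d in kuhn_from_a1.items():
        print(f"A1 = {d['A1_per_nm']:.2e}/nm ({label}) -> a = {d['kuhn_nm']:.2f} nm "
              f"= {d['kuhn_bp']:.1f} bp")


if __name__ == "__main__":
    main()
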