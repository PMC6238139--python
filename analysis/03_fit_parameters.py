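"""Recover the physical parameters from the simulated profile.

Fits the trial function A0(1 + A1·l(s))^(-3/2) to the Monte-Carlo profile
from analysis/02 over 1 bp – 10 Kbp (sigma fixed at 75 nm), derives kappa,
the Kuhn length and N_t, and runs the power-law-exponent diagnostic.
Regenerates the profile if results/fjc_profile.tsv is absent.
"""

import json
from pathlib import Path

from parbcage import (
    F_PLASMID,
    ParSSite,
    SimulationConfig,
    derive_params,
    fit_nc,
    fit_powerlaw_exponent,
    read_profile_tsv,
    simulate_profile,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    p = F_PLASMID
    src = RESULTS / "fjc_profile.tsv"
    if src.exists():
        prof = read_profile_tsv(src)
    else:
        cfg = SimulationConfig(n_monomers=p.n_monomers, n_conformations=20_000, seed=1)
        prof = simulate_profile([ParSSite(0, int(p.kuhn_bp), 0, 1.0)], p, cfg)

    fit = fit_nc(prof, p.sigma_nm, window_bp=(1.0, 10_000.0))
    derived = derive_params(fit, p.sigma_nm, p.enriched_length_bp)
    slope = fit_powerlaw_exponent(prof, p, window_bp=(1.0, 10_000.0))

    out = fit.to_dict() | {"powerlaw_exponent": slope}
    (RESULTS / "fit_parameters.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"A0 (kappa) = {fit.a0:.3f}; A1 = {fit.a1_per_nm:.3e}/nm; "
          f"a = {fit.kuhn_nm:.2f} nm = {fit.kuhn_bp:.1f} bp; "
          f"N_t = {derived.n_total:.0f} over {derived.enriched_length_bp/1000:.0f} Kbp.")
    print(f"Power-law diagnostic: slope {slope:.3f} "
          f"(the caging model predicts -3/2).")


if __name__ == "__main__":
    main()
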