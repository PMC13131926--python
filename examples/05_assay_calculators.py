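"""Assay mathematics: PAMPA permeability, dimer KD, cytotoxicity, fold
change."""

from cyclopept import (
    CytotoxMeasurement,
    PampaWell,
    classify_permeability,
    fold_change,
    fraction_dimer_from_kd,
    kd_from_fraction_dimer,
    pampa_pe,
    percent_cytotoxicity,
)

# --- PAMPA: donor 300 uL, acceptor 200 uL, 17 h, 0.3 cm^2 membrane
well = PampaWell(cd_t=8.0, ca_t=3.0, c0=10.0)
res = pampa_pe(well)
print(f"Ceq        {res.ceq:.3f} mM")
print(f"retention  {res.retention:.3f}")
print(f"Pe         {res.pe:.3e} cm/s ({res.pe_nm_s:.1f} nm/s)")
print(f"class      {classify_permeability(res.pe)} permeability (cutoff 1.5e-6 cm/s = 15 nm/s)")

# --- monomer-dimer equilibrium (mass photometry)
eq = kd_from_fraction_dimer(fraction_dimer=0.8644, p_total=9.4)
print(f"\nKD from FD=0.8644 at 9.4 nM total: {eq.kd:.2f} nM "
      f"(monomer {eq.monomer:.2f} nM, dimer {eq.dimer:.2f} nM)")
back = fraction_dimer_from_kd(eq.kd, 9.4)
print(f"inverse check: FD({eq.kd:.2f} nM) = {back.fraction_dimer:.4f}")

# --- LDH cytotoxicity
pct = percent_cytotoxicity(CytotoxMeasurement(experimental=2600.0, background=200.0, maximum=5000.0))
print(f"\npercent cytotoxicity: {pct:.1f}%")

# --- luminescence fold change
print(f"fold change: {fold_change(2.94e6, 1.02e6):.2f}x")

# Pe comes from the mass-balance closed form -ln(1 - CA/Ceq) normalised by
# membrane area, volumes and time; KD uses the monomer^2/dimer convention
# in chain-concentration units, so KD and the fraction-dimer observable
# form an exact inverse pair.
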