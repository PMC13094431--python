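"""Annotate an observed imaging m/z by accurate-mass search.

Builds the packaged combinatorial lipid database, searches a negative-mode
feature at m/z 295.23 within +/-0.05 Da, and prints the candidate
(lipid, adduct) explanations ranked by ppm deviation.  The top hit is the
oxidized fatty acid FA(18:2;O) as [M-H]-, the species this feature is
reported as in adipose tissue.
"""

from lipidmsi import accurate_mass_search, default_database

db = default_database()
hits = accurate_mass_search(295.23, "negative", db, tol_da=0.05)
print(f"{len(hits)} candidates for m/z 295.23 (negative mode):")
for h in hits[:5]:
    print(f"  {h.lipid.species_name:>12s} {h.adduct.name:>10s}  "
          f"theoretical {h.theoretical_mz:.4f}  delta {h.delta_ppm:+6.1f} ppm")
print("Smaller |delta ppm| means a closer mass match; MS2 evidence is "
      "needed to rank isobars confidently.")
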