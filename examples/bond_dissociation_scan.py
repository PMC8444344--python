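"""Interaction energy along the H-H bond-dissociation curve.

Scans the stretched-monomer bond length with SAPT(CAS(2,2)) — the GVB
level — and prints a CSV of the components.  The electrostatic and
exchange terms grow as the breaking bond makes the monomer more diffuse
and more polarizable, while the single-reference HF-based description
would fail qualitatively in this regime.
"""

from saptmc import DimerJob, run_sapt, scan
from saptmc.core.geometry import h2_dimer_tshape


def job_at(r_hh):
    mola, molb = h2_dimer_tshape(r_hh, 1.44, 6.21, convention="nearest-atoms")
    return DimerJob(mola, molb, "aug-cc-pvdz", "cas(2,2)", "cas(2,2)")


grid = [1.37, 1.44, 2.0, 3.0, 4.5, 6.0, 7.2]
rows = scan(job_at, grid)
cols = ("e_elst", "e_exch", "e_ind_plus", "e_exch_ind", "e_disp_plus",
        "e_exch_disp", "e_int")
print("r_hh," + ",".join(cols) + "   (mE_h)")
for row in rows:
    vals = ",".join(f"{row[c] * 1e3:8.4f}" for c in cols)
    print(f"{row['point']:4.2f},{vals}")

print("\nEach row is one stretched geometry; e_int is the total interaction"
      "\nenergy through second order. The smooth evolution across the"
      "\nrecoupling region (r ~ 3-5 bohr) is the multiconfigurational"
      "\ntreatment at work.")
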