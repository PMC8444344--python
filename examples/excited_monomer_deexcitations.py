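"""Dispersion of an electronically excited monomer: de-excitation terms.

An excited monomer's linear response contains negative transition energies
(de-excitations to lower states).  Response solvers built on excitation
operators miss them, so the package restores their induction/dispersion
content from separate response calculations on each lower state.  This
example uses the doubly-excited singlet of H2 described exactly (FCI
monomers), where the equivalence of the two routes is exact.
"""

from saptmc import DimerJob, MonomerWorkspace, run_sapt
from saptmc.core.geometry import h2_dimer_tshape

mola, molb = h2_dimer_tshape(1.44, 1.44, 5.0)

ws = None
for label, neg in (("with de-excitation corrections", True),
                   ("positive transitions only", False)):
    job = DimerJob(mola, molb, "6-31g**", "fci", "fci", state_a=1,
                   negative_transitions=neg)
    if ws is None:
        ws = MonomerWorkspace(job)
    comps = run_sapt(job, ws)
    print(f"\n--- excited monomer A (state 1), {label} ---")
    print(f"  E_disp+(2)    {comps.e_disp_plus * 1e3:9.3f} mE_h")
    print(f"  sum eps_disp  {comps.eps_disp_sum * 1e3:9.3f} mE_h")
    print(f"  sum eps_ind   {comps.eps_ind_sum * 1e3:9.3f} mE_h")
    print(f"  E_int         {comps.e_int * 1e3:9.3f} mE_h")

print("""
The de-excitation corrections (eps rows) are recovered from the response
of the states BELOW the reference, where the same transition appears with
a positive energy.  Dropping them (second block) loses a sizable part of
the dispersion attraction; for this symmetric arrangement the induction
counterpart vanishes by symmetry.""")
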