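"""Score KEGG module completeness for a genome's KO repertoire.

The denitrification module has four steps (nitrate -> nitrite -> nitric
oxide -> nitrous oxide -> N2).  A genome with three of the four steps is
75% complete and is called present at the default cutoff.
"""

from cycleprofiler import call_presence, load_templates, module_completeness

template = load_templates()
defn = template.modules["M00529"]  # denitrification
print(f"{defn.module_id} ({defn.name}): {defn.n_steps} steps")
print(f"definition: {defn.definition}")

kos = {"K00370", "K00371", "K00368", "K04561", "K02305"}  # nosZ (K00376) missing
call = call_presence(module_completeness(defn, kos))
print(f"KOs present: {sorted(kos)}")
print(f"step states: {call.step_states}")
print(f"completeness: {call.completeness:.2f} -> present: {call.present}")
print()
print("Three of four steps are satisfied (nitrous oxide reduction lacks nosZ);")
print("75% completeness meets the default cutoff, so the module is called present.")
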