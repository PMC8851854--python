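"""Annotate proteins from a domtblout table, then motif-validate the hits.

Two proteins both score above the cutoff of the KO family K11179, which
contains the functionally divergent pair DsrC (dissimilatory sulfite
reduction) and TusE (tRNA thiolation).  Only the protein carrying the
conserved DsrC residue window survives motif validation.
"""

import numpy as np

from cycleprofiler import DSRC_MOTIF, MotifRule, select_hits, validate_hits
from cycleprofiler.fixtures import format_domtblout_row, sequence_matching_motif
from cycleprofiler.hmm import parse_domtblout
from cycleprofiler.templates import load_templates

template = load_templates()
specs = template.profile_specs
rules = template.motif_rules
cutoff = specs["K11179"].cutoff_score

rows = [
    format_domtblout_row("dsrC_like", "K11179", tlen=110, qlen=105,
                         full_evalue=1e-40, full_score=cutoff + 30,
                         i_evalue=1e-38, dom_score=cutoff + 28,
                         hmm_from=1, hmm_to=105, ali_from=1, ali_to=105),
    format_domtblout_row("tusE_like", "K11179", tlen=110, qlen=105,
                         full_evalue=1e-35, full_score=cutoff + 20,
                         i_evalue=1e-33, dom_score=cutoff + 18,
                         hmm_from=1, hmm_to=105, ali_from=1, ali_to=105),
]
rng = np.random.default_rng(0)
sequences = {
    "dsrC_like": "MSE" + sequence_matching_motif(rng, DSRC_MOTIF) + "KKL",
    "tusE_like": "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100)),
}

table = select_hits(parse_domtblout(rows, genome_id="demo"), specs)
table = validate_hits(table, sequences, rules, specs)
print(table[["protein_id", "profile_id", "passed_threshold", "passed_motif", "winning"]])
print()
print("Both hits clear the bit-score cutoff, but only the protein with the")
print(f"conserved window {DSRC_MOTIF} is kept as DsrC (winning=True);")
print("the TusE-like homolog is rejected despite its high score.")
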