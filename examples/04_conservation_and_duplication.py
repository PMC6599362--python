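"""Annotate a prediction with conservation and duplication evidence.

Aligns known mature miRNAs onto a precursor under the <=3-edit /
no-consecutive-indel rule, and scans the genome for extra copies of the
guide to compute its weight.
"""

from plantmir import fixtures as fx
from plantmir.annotate import align_to_known_matures, compute_weight, find_genomic_occurrences

planted = fx.make_reference_locus()
guide_iv = (planted.guide_offset, planted.guide_offset + len(planted.guide_seq))

db = [
    ("mir-known-exact", planted.guide_seq),
    ("mir-known-2mm", "AGAUAUUACUGCGGUUCACUC"),  # 2 substitutions
    ("mir-unrelated", "UUUGGAUUGAAGGGAGCUCUA"),
]
hits = align_to_known_matures(planted.precursor_seq, db, guide_interval=guide_iv)
for h in hits:
    flag = "double-checked" if h.overlaps_guide else "checked"
    print(f"{h.db_id}: {h.n_edits} edits at [{h.local_start},{h.local_end}) -> {flag}")

genome, _ = fx.make_genome([planted], length=5000, seed=11)
occ = find_genomic_occurrences(planted.guide_seq, genome)
print(f"guide occurs {len(occ)}x in the genome -> weight "
      f"{compute_weight(planted.guide_copies, max(1, len(occ)))}")
# Hits overlapping the guide locus are the strongest conservation signal;
# multi-copy guides get their read support down-weighted accordingly.
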