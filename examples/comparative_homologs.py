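"""Cross-species day/night comparison on the packaged homolog tables.

Applies the inclusive >=3-fold day/night filter to the 14 coral-larva
homolog count pairs (table3) and joins a DCG list against the adult coral
homolog table (table2).
"""

from dielrhythm import fold_change_filter, overlap_dcgs, packaged_table
from dielrhythm.comparative import table_pairs

t3 = packaged_table("table3")
day_up, night_up = fold_change_filter(table_pairs(t3), threshold=3.0)
print(f"{len(day_up)} day-upregulated, {len(night_up)} night-upregulated homologs")
for p in day_up:
    print(f"  day   {p.nv_gene_id:>6}  {p.day_count:>5}/{p.night_count:<5} {p.annotation}")
for p in night_up:
    print(f"  night {p.nv_gene_id:>6}  {p.day_count:>5}/{p.night_count:<5} {p.annotation}")

t2 = packaged_table("table2")
dcgs = list(t2["nv_gene_id"]) + ["000001"]  # one unmapped id for illustration
joined, unmapped = overlap_dcgs(dcgs, t2)
print(f"\nadult-coral homolog join: {len(joined)} matched rows, {unmapped} DCG unmapped")
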