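"""The packaged worked example: 49 confirmed transcripts.

Pushes the shipped pre-joined result table (49 dysregulated transcripts
with discovery and confirmation FDRs) through the confirm -> partition ->
novelty chain and prints the headline accounting.
"""

from lnckit import (
    annotate_novelty,
    confirm,
    load_known_lncrnas,
    partition_by_direction,
)
from lnckit.confirm import table2_cohorts

discovery, confirmation = table2_cohorts()
hits = confirm(discovery, confirmation, fdr_disc=0.2, fdr_conf=0.05)
known = load_known_lncrnas()
hits = annotate_novelty(hits, known)
up, down = partition_by_direction(hits)

print(f"confirmed transcripts: {len(hits)}")
print(f"  up-regulated:   {len(up)} (strongest: "
      f"{hits.loc[hits['log2fc'].idxmax(), 'symbol']}, log2FC "
      f"{hits['log2fc'].max():+.3f})")
print(f"  down-regulated: {len(down)} (strongest: "
      f"{hits.loc[hits['log2fc'].idxmin(), 'symbol']}, log2FC "
      f"{hits['log2fc'].min():+.3f})")
print(f"  novel:          {int(hits['novel'].sum())} "
      f"(known set of {len(known)}: {', '.join(sorted(known))})")
print("Every row passes FDR<0.2 (3-pair cohort) and FDR<0.05 (confirmation");
print("cohort); 'novel' means the symbol has no prior literature annotation.")
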