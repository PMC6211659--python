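"""In-silico specificity screen of the river herring qPCR assay.

Runs the published primer/probe set against the packaged synthetic CO1
reference panel and prints, per species, the amplicon length and the
mismatch counts of each oligo.  The two target species (alewife and
blueback herring) should match every oligo exactly; closely related
shads carry increasing mismatch loads; distant taxa yield no amplicon
at all at the default search stringency.
"""

from alosaedna import RIVER_HERRING_OLIGOS, probe_mismatch_table
from alosaedna.simulate import synthetic_reference_set

refs = synthetic_reference_set()
table = probe_mismatch_table(refs, RIVER_HERRING_OLIGOS)

summary = (table.groupby("species", sort=False)
           .agg(n=("label", "size"), alignable=("alignable", "all"),
                length=("length", "first"), fwd_mm=("fwd_mm", "first"),
                rev_mm=("rev_mm", "first"), probe_mm=("probe_mm", "first")))
print(summary.to_string())
print()
print("A species with alignable=False never yields an amplicon within the")
print("3-mismatch search limit — the assay cannot amplify it at all.")
print("Both river herring show a 164 bp amplicon with 0 mismatches on every")
print("oligo; the probe-loop mismatch column orders the off-target risk.")
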