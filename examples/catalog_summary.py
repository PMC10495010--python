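"""Family and class composition of the Arabidopsis redoxin catalog.

The packaged catalog lists the thioredoxins (Trx) and glutaredoxins (Grx)
of Arabidopsis thaliana with their active-site motifs.  The motif alone
determines the Grx class: CC... motifs mark the land-plant-specific
class III (ROXY) proteins, CGFS marks class II, anything else CxxC-like
is class I.
"""

from epsim import load_redoxin_catalog, classify_redoxin_motif
from epsim.pipeline import run_catalog_summary

summary = run_catalog_summary()
print(f"catalog entries: {summary['n_entries']}")
print(f"families:        {summary['family_counts']}")
print(f"Grx classes:     {summary['grx_class_counts']}")

print("\nclass III (CC-type/ROXY) glutaredoxins:")
for e in load_redoxin_catalog():
    if classify_redoxin_motif(e) == "III":
        print(f"  {e.protein_name:<8s} {e.uniprot_id}  {e.active_site_motif}")

# The class III count (21) is the headline statistic: about two thirds of
# the Grx family in this plant belongs to the group that exists only in
# land plants.
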