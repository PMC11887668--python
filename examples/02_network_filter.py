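"""Filter screen hits by physical-interaction corroboration and orthology.

A hit that physically interacts with at least one other hit is less likely
to be an off-target artifact.  Survivors are mapped to human orthologs and
grouped into connected components (putative functional groups).
"""

import io

from slscreen import filter_by_orthologs, filter_hits_by_network, group_hits, load_edge_list, load_ortholog_map

edges = io.StringIO(
    "gene_a\tgene_b\tscore\tchannel\n"
    "Atg8b\tAtg1\t0.92\tphysical\n"
    "Atg1\tAtg13\t0.88\tphysical\n"
    "Pi3K59F\tAtg1\t0.75\tphysical\n"
    "wde\tegg\t0.81\tphysical\n"
    "Rab7\tlight\t0.55\tphysical\n"
)
orthologs = io.StringIO(
    "fly_gene\thuman_gene\tconfidence\n"
    "Atg8b\tGABARAP\t0.95\n"
    "Atg8b\tGABARAPL1\t0.80\n"
    "Atg1\tULK1\t0.90\n"
    "Atg13\tATG13\t0.85\n"
    "wde\tTNRC6A\t0.40\n"
)

hits = {"Atg8b", "Atg1", "Atg13", "wde", "Rab7", "orphan_gene"}
network = load_edge_list(edges, min_score=0.4, channels=["physical"])

retained = filter_hits_by_network(hits, network)
mapped = filter_by_orthologs(retained, load_ortholog_map(orthologs), min_confidence=0.5)
groups = group_hits(set(mapped["source_gene"]), network)

print(f"screen hits:                  {len(hits)}")
print(f"network-corroborated:         {sorted(retained)}")
print(f"with human orthologs (>=0.5): {sorted(set(mapped['source_gene']))}")
print(f"  expanding to human genes:   {sorted(mapped['target_gene'])}")
print(f"functional groups:            {groups}")
# 'wde', 'Rab7' and 'orphan_gene' drop out (their partners are not co-hits);
# the Atg genes survive as one connected group, and one fly gene (Atg8b)
# expands to two human genes.
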