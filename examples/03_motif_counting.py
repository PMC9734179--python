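"""Count GAGA/GAG motifs, overlaps allowed, in TSS-upstream windows.

Plants a known GA-rich density upstream of a gene, extracts the 2-kb
gene-oriented upstream window, and tallies motifs the way promoter scans
do: every start position counts, so 'GAGAG' is one GAGA and two GAGs.
"""

from mbchip import count_overlapping, extract_upstream
from mbchip.models import GeneModel
from mbchip.motifs import species_motif_table
from mbchip.regions import GenomicInterval
from mbchip.simulate import generate_genome, plant_upstream_motifs

print("counting rule:")
for seq in ("GAGA", "GAGAG"):
    print(f"  {seq}: {count_overlapping(seq, 'GAGA')} GAGA, {count_overlapping(seq, 'GAG')} GAG")

genome = generate_genome(seed=1, contigs={"c1": 30_000}, gc=0.35)
gene = GeneModel(
    gene_id="Mblk1_like",
    span=GenomicInterval("c1", 12_000, 18_000, "+"),
    exons=(GenomicInterval("c1", 12_000, 18_000, "+"),),
)
window = GenomicInterval("c1", 10_000, 12_000)  # the 2 kb upstream of the TSS
genome, truth = plant_upstream_motifs(genome, window, gaga_n=37, gag_n=112, seed=2)

upstream = extract_upstream(gene, genome, length=2_000)
table = species_motif_table([upstream], window_lengths=(2_000,))
print("\nplanted truth :", truth)
print(table.to_string(index=False))
# Realized counts exceed the request because background sequence and
# GAGs embedded in planted GAGAs also count; the table must match the
# generator's recorded realized values exactly.
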