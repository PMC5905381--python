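"""Assemble a two-locus multiplexed pool into separate consensi.

Pools 300 reads of a 500 bp locus with 60 reads of an 850 bp locus,
clusters the mixture, builds and polishes one consensus per cluster, and
scores each against its own truth.
"""

from ampcon.consensus import assemble_multiplexed
from ampcon.evaluate import best_orientation_report
from ampcon.polish import polish_consensus, trim_consensus
from ampcon.seqio import SeqRecord
from ampcon.simulate import LocusSpec, RunConfig, default_primer_pair, random_truth, simulate_run

truth_a = SeqRecord("locusA", random_truth(500, [1, 10]))
truth_b = SeqRecord("locusB", random_truth(850, [1, 11]))
config = RunConfig(
    loci=[LocusSpec("locusA", truth_a, "BC01", 300), LocusSpec("locusB", truth_b, "BC02", 60)],
    seed=1,
)
run = simulate_run(config)

contigs = assemble_multiplexed(run.reads, n_loci=2)
by_id = {r.id: r for r in run.reads}
for contig, truth, label in zip(contigs, (truth_a, truth_b), ("locusA", "locusB")):
    cluster = [by_id[i] for i in contig.cluster_read_ids]
    polished, _ = polish_consensus(contig, cluster)
    trimmed, _ = trim_consensus(polished, default_primer_pair(label))
    acc = best_orientation_report(trimmed.seq, truth)
    print(f"{label}: {contig.support} reads -> {len(trimmed.seq)} bp consensus, "
          f"{acc.rounded()}% identity to truth")
print("Distinct loci land in distinct clusters, so one sequencing run can")
print("carry multiple markers per sample without cross-contamination of the")
print("consensi.")
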