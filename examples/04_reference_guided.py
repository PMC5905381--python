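"""Reference-guided consensus against a divergent congener, vs de novo.

Maps reads to a 3%-divergent reference, calls the pileup majority
consensus (reference bases fill uncovered columns), polishes, and
compares the result with the de novo pipeline on the same reads.
"""

import numpy as np

from ampcon.evaluate import compare_strategies
from ampcon.pipeline import denovo_strategy
from ampcon.refmap import refguided_pipeline
from ampcon.seqio import SeqRecord
from ampcon.simulate import LocusSpec, RunConfig, default_primer_pair, random_truth, simulate_run


def diverge(seq: str, frac: float, seed: int) -> str:
    rng = np.random.default_rng(seed)
    s = list(seq)
    for i in rng.choice(len(seq), size=int(frac * len(seq)), replace=False):
        s[i] = "ACGT"[("ACGT".index(s[i]) + rng.integers(1, 4)) % 4]
    return "".join(s)


truth = SeqRecord("16S_toy", random_truth(500, [1, 0]))
reference = SeqRecord("congener", diverge(truth.seq, 0.03, 99))
reads = simulate_run(RunConfig(loci=[LocusSpec("16S_toy", truth, "BC01", 30)], seed=5)).reads

refmap = refguided_pipeline(reads, reference)
print(f"reference-guided: {refmap.n_mapped}/{refmap.n_reads} reads mapped to {refmap.ref_id}")

denovo = denovo_strategy(primers=default_primer_pair("16S_toy"))(reads)
rep_dn, rep_rm, delta = compare_strategies(denovo, refmap.contig, truth)
print(f"de novo identity:          {rep_dn.rounded()}%")
print(f"reference-guided identity: {rep_rm.rounded()}%")
print(f"delta (de novo - refmap):  {delta:+.1f} percentage points")
print("With reads covering the whole amplicon, majority calling corrects the")
print("reference's divergent sites; only uncovered columns inherit reference")
print("content. De novo needs no reference at all, which is why it is the")
print("default strategy.")
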