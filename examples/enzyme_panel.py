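"""Evaluate the seven blunt 4-cutter enzymes on a synthetic genome.

Digests a 500 kb simulated reference with each candidate enzyme, applies
70-200 bp size selection, and prints the evaluation panel: fragment counts,
the fraction of the genome captured (complexity reduction), tag density,
and the SNP yield predicted from a 1-SNP-per-5,000-bp divergence rate.
A low complexity-reduction % means deeper coverage per sequencing run;
the best library enzyme balances fragment yield against repeat content.
"""

from rrsnp import (BUILTIN_ENZYMES, SimConfig, compute_digest_report, digest,
                   make_parent_genomes, reports_to_frame)

config = SimConfig(genome_length=500_000, seed=42)
genomes = make_parent_genomes(config)
genome_length = sum(len(s) for s in genomes.reference.values())

reports = []
for enzyme in BUILTIN_ENZYMES.values():
    fragments = digest(genomes.reference, enzyme)
    reports.append(
        compute_digest_report(
            fragments, genome_length, genomes.repeats, enzyme_name=enzyme.name
        )
    )

frame = reports_to_frame(reports)
print(frame.round(2).to_string(index=False))
print(
    "\nEach row: total fragments from the digest, fragments kept by 70-200 bp\n"
    "size selection, their summed length, the percent of the genome they\n"
    "represent, fold coverage a 1.92 Gb run would give them, 33-bp tags per\n"
    "Mbp, SNPs expected at 1/5,000 bp divergence, and how many selected\n"
    "fragments carry a repetitive terminal tag."
)
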