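"""LD estimation and block pruning of the significant SNP set.

Computes pairwise dosage r^2 among the significant SNPs, partitions them
into blocks (connected components at r^2 >= 0.5), and keeps the most
strongly associated SNP per block -- the step that turns a "model 2" SNP
set into a "model 3" set.
"""

from polyrisk import (
    apply_snp_filters,
    associate_all,
    ld_blocks,
    ld_matrix,
    paper_like_panel,
    prune_by_ld,
    significant_snps,
    simulate_cohort,
)

train, _ = simulate_cohort(paper_like_panel(seed=42))
filtered, _ = apply_snp_filters(train.gm, train.phen)
assoc = associate_all(filtered, train.phen)
sig = significant_snps(assoc)
print(f"{len(sig)} significant SNPs before pruning")

lm = ld_matrix(filtered, [r.snp_id for r in sig])
for block in ld_blocks(lm, threshold=0.5):
    if len(block) > 1:
        print(f"LD block: {block}")

kept, log = prune_by_ld(sig, lm, filtered, threshold=0.5)
print(f"\n{len(kept)} SNPs kept after pruning")
for rec in log:
    print(f"  removed {rec.removed_snp} (r^2 to kept {rec.kept_snp}: {rec.r2_to_kept:.2f})")
# The 4-SNP simulated block collapses to its single best SNP; singleton
# blocks pass through untouched.
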