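"""A miniature three-arm screen with known ground truth.

Generates per-gene counts for control / nanos-KD / mata-KD arms under
five truth mechanisms, classifies every gene with the screen decision
table, and prints the confusion between truth and call.  Prophase-specific
positives (significant with mata, not with nanos) are the cohesion-
rejuvenation candidates; arms below the sterility threshold are excluded.
"""

from flyndj import generate_synthetic_screen, run_screen

truth_mix = {
    "geneA": "rejuvenation_only",
    "geneB": "rejuvenation_only",
    "geneC": "s_phase_and_prophase",
    "geneD": "s_phase_only",
    "geneE": "sterile",
    "geneF": "null",
    "geneG": "null",
}

manifest, truth = generate_synthetic_screen(truth_mix, n_progeny_per_arm=800, seed=12)
results = run_screen(manifest, alpha=0.05, n_replicates=5000, seed=13)
merged = results.merge(truth, on="gene")

print(f"{'gene':6s} {'mechanism':22s} {'category':22s} {'%NDJ mata':>9s} {'%NDJ nanos':>10s}")
for row in merged.itertuples(index=False):
    print(
        f"{row.gene:6s} {row.mechanism:22s} {row.category:22s} "
        f"{row.pct_ndj_mata:9.2f} {row.pct_ndj_nanos:10.2f}"
    )
agree = (merged["category"] == merged["expected_category"]).mean()
print(f"\ntruth-category agreement: {100 * agree:.0f}%")
print(
    "\nnull genes land in 'negative' (up to the 5% false-positive rate);\n"
    "sterile nanos arms are excluded rather than miscalled prophase-specific."
)
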