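"""Scanning survey data for synergistic triplets, with known ground truth.

Generates a geriatric-screening-style binary table with 5 planted noisy-XOR triplets,
runs the full pipeline (low-MI triangle filter -> O-information ->
permutation p-values -> Benjamini-Hochberg), and scores recovery against
the generator's manifest.
"""

import synergynet as sn

cfg_gen = sn.SurveyGenConfig(
    n_subjects=5000, n_signs=15, n_diseases=0,
    n_planted_triplets=5, n_planted_pairs=0, flip_noise=0.05, seed=42,
)
data, manifest = sn.generate_survey(cfg_gen)
print(f"Survey table: {data.n} subjects x {data.m} signs; 5 planted XOR triplets.")

results = sn.scan(data, sn.ScanConfig(mi_threshold=0.05, permutations=1000, fdr_q=0.15, seed=43))
print(f"Candidates after the MI<0.05 triangle filter: {len(results)}")

planted = set(manifest.triplet_label_sets())
print("\nTop of the result list (sorted by q, then O-information):")
print("  triple                    omega_bits  p        q        planted")
for r in results[:8]:
    mark = "yes" if frozenset(r.labels) in planted else "no"
    print(
        f"  {'-'.join(r.labels):<24}  {r.omega:+.3f}     "
        f"{r.p_value:.4f}   {r.q_value:.4f}   {mark}"
    )

significant = {frozenset(r.labels) for r in results if r.significant}
recovered = sum(1 for t in planted if t in significant)
false_pos = len(significant - planted)
print(f"\nRecovered {recovered}/5 planted triplets; {false_pos} non-planted flagged.")
print("Strongly negative O-information with a tiny permutation p-value is the")
print("signature of synergy that the pairwise filter had already declared 'no")
print("association'.")

# The clinical-style view of one recovered triple:
a, b, c = sorted(manifest.planted_triplets[0]["labels"])
profile = sn.conditional_profile(data, c, [a, b])
print(f"\nConditional prevalences of {c}:")
print(profile)
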