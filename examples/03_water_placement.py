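"""Score predicted water placements against crystal waters.

Builds structure fixtures whose "predicted" waters are the crystal
waters displaced by a controlled distance, then scores them with the
1 Å-cutoff one-to-one matching used for hydration-site evaluation.
"""

import rbfebench as rb

for displacement in (0.0, 0.5, 1.5):
    results = []
    for seed in range(5):
        ref, predicted = rb.gen_structure_fixture(
            rb.FixtureSpec(n_waters=5, displacement=displacement, seed=seed)
        )
        crystal = rb.binding_site_waters(ref, cutoff=5.0)
        results.append(rb.match_waters(predicted, crystal, cutoff=1.0))
    mean, se = rb.prediction_percentage(results, n_boot=5000, seed=1)
    print(f"displacement {displacement:.1f} A -> placement accuracy {mean:5.1f} ± {se:4.1f} %")

# Sub-cutoff displacements keep every predicted water within 1 A of its
# crystal partner (100%); displacements beyond the cutoff leave none (0%).
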