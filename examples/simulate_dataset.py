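"""Generate a synthetic oocyte proteome and both simulated experiments.

The ground truth fixes each protein's nuclear/cytosolic concentration,
its RanGTP-dependent binding strength and background binding; the two
intensity tables are what a mass spectrometer would report (proteoform-
expanded, noisy, left-censored at the detection limit).
"""

import exportome as ex

params = ex.SimulationParams(seed=42)
truth = ex.generate_ground_truth(1000, params)
spike = ex.make_spike_standard(6, 8, 0.5, 10.0)

fraction = ex.simulate_fraction_intensities(truth, spike, params, n_replicates=3)
affinity = ex.simulate_affinity_experiment(truth, params)

total = truth["true_conc_nuc"] + truth["true_conc_cyt"]
print("ground truth:", len(truth), "proteins,",
      f"abundance span {total.max() / total.min():.1e}-fold")
print("cargo strata:", truth["stratum"].value_counts().to_dict())
print("compartments:", truth["compartment_class"].value_counts().to_dict())
print("spike-in standard:", len(spike), "proteins at amounts",
      [float(a) for a in sorted(spike["amount_fmol"].unique())], "fmol")
print("fractionation table:", len(fraction), "rows;",
      f"{fraction['intensity'].isna().mean():.1%} censored below the detection limit")
print("affinity table:", len(affinity), "rows across samples",
      sorted(affinity["sample_id"].unique()))
# The censored share is the price of a 5-decade dynamic range: the bottom of
# the abundance spectrum falls below what the instrument can detect.
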