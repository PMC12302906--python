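"""Catching annotation errors: plate swaps and genotype mismatches.

Growth temperature leaves a strong transcriptome signature, so nominal
temperature can be predicted from expression.  Training a sparse regression
with one plate held out flags plates whose labels disagree with their
predicted temperatures; an exhaustive search over pairings of flagged
plates proposes the annotation exchange that minimizes total error, and a
second prediction round verifies it.  Independently, cultivar-specific SNP
calls are checked against the nominal cultivar.
"""

from fieldfit import genotype_concordance, infer_swaps, loo_plate_temperature
from fieldfit.qc import verify_correction
from fieldfit.synthdata import inject_plate_swap, make_qc_study, make_snp_fixture

bundle = make_qc_study(seed=1)
swapped = inject_plate_swap(bundle.study, "P09", "P11")
swapped = inject_plate_swap(swapped, "P10", "P12")

preds = loo_plate_temperature(swapped, seed=0)
print("per-plate MAE of predicted vs nominal temperature (degC):")
for p in preds:
    print(f"  {p.plate_id}: {p.mae:5.2f}")

proposal = infer_swaps(preds)
print(f"\nflag threshold {proposal.threshold:.2f} degC; proposed exchanges: "
      f"{proposal.pairs}")

preds2, accepted = verify_correction(swapped, proposal)
print(f"after re-annotation, max plate MAE {max(p.mae for p in preds2):.2f}; "
      f"correction accepted: {accepted}")

# genotype concordance on three samples: clean A, clean B, and a mixture
calls = make_snp_fixture(2000, 3, ["A", "B", "mix"], error_rate=0.02,
                         dropout_rate=0.1, seed=1)
reports = genotype_concordance(calls, {"s000": "A", "s001": "B", "s002": "A"})
print("\ngenotype concordance:")
for r in reports:
    print(f"  {r.sample_id}: {r.prop_match_nominal:.2f} of {r.n_called} "
          f"loci match nominal -> {r.verdict}")
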