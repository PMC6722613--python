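"""Generate a synthetic splicing-event dataset and apply the quality filters.

The generator plants canonical splice-site motifs (acceptor pyrimidine
tract + AG; donor GT-rich 7-mer) at every exon junction of a random
genome, plus class-dependent extras: secondary splice sites for ALT3/ALT5
exons and intronic silencers for cassette (ES) exons.
"""

from splicecnn import FilterThresholds, apply_quality_filters, stratify_by_frequency
from splicecnn.synth import SynthConfig, generate_adversarial_table, generate_dataset

ds = generate_dataset(SynthConfig(scale=0.01, seed=1))
print(f"generated {len(ds.events)} events on {len(ds.genome)} synthetic chromosome(s)")
for cls in ("CON", "ES", "ALT3", "ALT5"):
    n = sum(e.as_class == cls for e in ds.events)
    print(f"  {cls:5s} {n:4d} events")

kept, rejected = apply_quality_filters(ds.events, FilterThresholds())
print(f"quality filters: kept {len(kept)}, rejected {len(rejected)} "
      "(clean synthetic data passes by construction)")

strata = stratify_by_frequency([e for e in kept if e.as_class != "CON"], cutoff=0.8)
n_high = sum(s == "HEvents" for s in strata.values())
print(f"frequency strata: {n_high} HEvents (level > 0.8), "
      f"{len(strata) - n_high} MREvents — the bimodal level distribution "
      "puts most alternative events near 0 or 1")

# the adversarial battery plants exactly one filter violation per record
events, expected = generate_adversarial_table()
kept, rejected = apply_quality_filters(events)
print(f"\nadversarial battery: {len(kept)}/{len(events)} kept; rejections:")
for r in rejected:
    print(f"  {r.event.event_id:14s} -> {r.rule}")
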