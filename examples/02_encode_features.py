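"""Extract and encode the model inputs for one event.

Each event is represented by two 140-nt windows (±70 nt around the
acceptor and donor junctions, transcript-oriented), one-hot encoded to
140×4 matrices, plus the z-normalized length triple (L1 upstream intron,
L2 exon, L3 downstream intron).
"""

from splicecnn import compute_length_stats, extract_junction_windows, length_features, one_hot_encode
from splicecnn.synth import SynthConfig, generate_dataset

ds = generate_dataset(SynthConfig(scale=0.005, seed=2))
e = next(ev for ev in ds.events if ev.as_class == "CON")  # strong consensus sites
w = extract_junction_windows(e, ds.genome)

print(f"event {e.event_id} ({e.as_class}, strand {e.strand}, exon {e.exon_len} nt)")
print(f"acceptor window ...{w.acceptor_seq[60:80]}... (junction between pos 70/71)")
print(f"  intron end reads ...{w.acceptor_seq[56:70]} -> planted pyrimidine tract + AG")
print(f"donor window     ...{w.donor_seq[60:80]}...")
print(f"  intron start reads {w.donor_seq[70:77]} -> planted GT-rich donor site")

mat = one_hot_encode(w.acceptor_seq)
print(f"one-hot matrix shape {mat.shape}; every row sums to 1: {(mat.sum(axis=1) == 1).all()}")

stats = compute_length_stats(ds.events)
v = length_features(e, stats)
print(f"length stats: exon {stats.exon_mean:.0f}±{stats.exon_sd:.0f} nt, "
      f"intron {stats.intron_mean:.0f}±{stats.intron_sd:.0f} nt")
print(f"normalized (L1, L2, L3) = ({v[0]:+.2f}, {v[1]:+.2f}, {v[2]:+.2f}) "
      "— z-scores of this event's intron/exon/intron lengths")
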