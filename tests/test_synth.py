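"""Generator contracts: determinism, planted structure, level distributions."""

import numpy as np
import pytest

from splicecnn.events import apply_quality_filters
from splicecnn.features import extract_junction_windows
from splicecnn.synth import (
    ACCEPTOR_CONSENSUS,
    DONOR_CONSENSUS,
    SynthConfig,
    difficulty_gradient,
    generate_adversarial_table,
    generate_dataset,
)


class TestDeterminismAndBookkeeping:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SynthConfig(scale=0.002, seed=9)
        d1, d2 = generate_dataset(cfg), generate_dataset(cfg)
        for tag, ds in (("a", d1), ("b", d2)):
            ds.write(tmp_path / f"{tag}.fa", tmp_path / f"{tag}.tsv", tmp_path / f"{tag}.json")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_class_counts_match_request(self, small_synth):
        counts = SynthConfig(scale=0.01).counts()
        got = {c: sum(e.as_class == c for e in small_synth.events) for c in counts}
        assert got == counts

    def test_all_default_events_pass_filters(self, small_synth):
        kept, rejected = apply_quality_filters(small_synth.events)
        assert rejected == []
        assert len(kept) == len(small_synth.events)


class TestPlantedStructure:
    def test_junction_windows_carry_the_consensus_sites(self, small_synth):
        """Extraction round trip: windows re-extracted from the genome show
        the planted acceptor (...AG at the junction) and donor (GT...)
        consensus far above background on both strands."""
        acc_hits, don_hits, n = 0, 0, 0
        for e in small_synth.events[:300]:
            w = extract_junction_windows(e, small_synth.genome)
            # acceptor: intron end AG immediately left of the junction
            acc_hits += w.acceptor_seq[68:70] == "AG"
            don_hits += w.donor_seq[70:72] == "GT"
            n += 1
        # strength 0.9 per base -> expect ~0.8 of sites intact (vs ~1/16 background)
        assert acc_hits / n > 0.6
        assert don_hits / n > 0.6

    def test_secondary_acceptor_enriched_in_alt3_windows(self):
        """Two-proportion z on downstream-of-junction acceptor-like YAG
        (pyrimidine + AG) frequency, ALT3 vs CON, at 1000 events per class:
        the planted secondary site must be overwhelmingly detectable
        (z > 5).  Plain AG counting would be confounded because the
        secondary site's own pyrimidine tract suppresses background A/G in
        the same subregion."""
        ds = generate_dataset(
            SynthConfig(class_counts={"CON": 1000, "ES": 1, "ALT3": 1000, "ALT5": 1}, seed=21)
        )

        def yag_freq(events):
            hits = total = 0
            for e in events:
                w = extract_junction_windows(e, ds.genome).acceptor_seq
                exonic = w[72:101]  # downstream of the junction, secondary-offset range
                hits += sum(
                    exonic[i] in "CT" and exonic[i + 1 : i + 3] == "AG"
                    for i in range(len(exonic) - 2)
                )
                total += len(exonic) - 2
            return hits, total

        alt3 = [e for e in ds.events if e.as_class == "ALT3"]
        con = [e for e in ds.events if e.as_class == "CON"]
        h1, n1 = yag_freq(alt3)
        h2, n2 = yag_freq(con)
        p1, p2 = h1 / n1, h2 / n2
        pool = (h1 + h2) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        assert z > 5

    def test_es_inclusion_levels_are_bimodal(self):
        ds = generate_dataset(SynthConfig(class_counts={"CON": 1, "ES": 800, "ALT3": 1, "ALT5": 1}, seed=3))
        incl = np.array([e.incl_level for e in ds.events if e.as_class == "ES"])
        assert ((incl > 0.9).mean() + (incl < 0.1).mean()) > 0.5
        assert ((incl > 0) & (incl < 1)).all()

    def test_gradient_weakens_silencers_only_for_high_inclusion(self):
        cfg = SynthConfig(class_counts={"CON": 1, "ES": 600, "ALT3": 1, "ALT5": 1}, seed=4)
        ds = difficulty_gradient(cfg)
        by_level = {True: [], False: []}
        for rec, e in zip(ds.truth["events"], ds.events):
            if rec["class"] == "ES":
                by_level[e.incl_level > 0.8].append(rec["silencer_strength"])
        assert np.mean(by_level[True]) < np.mean(by_level[False])
        # control: without the gradient the strengths are constant
        ds0 = generate_dataset(cfg)
        strengths = {r["silencer_strength"] for r in ds0.truth["events"] if r["class"] == "ES"}
        assert strengths == {cfg.motif_strength}

    def test_ground_truth_pwms_have_planted_shape(self, small_synth):
        acc = np.array(small_synth.truth["motifs"]["acceptor_pwm"])
        don = np.array(small_synth.truth["motifs"]["donor_pwm"])
        assert acc.shape == (len(ACCEPTOR_CONSENSUS), 4)
        assert don.shape == (len(DONOR_CONSENSUS), 4)
        # donor consensus GT at the start, strength on the consensus base
        assert don[0].argmax() == 2 and don[1].argmax() == 3
        assert don[0].max() == pytest.approx(0.9)


class TestAdversarialBattery:
    def test_exactly_five_kept_one_violation_per_rule(self):
        events, expected = generate_adversarial_table()
        kept, rejected = apply_quality_filters(events)
        assert len(events) == 10 and len(kept) == 5
        assert {e.event_id for e in kept} == {k for k, v in expected.items() if v}
        rules = sorted(r.rule for r in rejected)
        assert rules == sorted(
            ["min_est_skipping", "min_est_altsite", "min_exon_len", "min_intron_len",
             "excluded_class"]
        )

    def test_planted_violations_have_named_reasons(self):
        events, _ = generate_adversarial_table()
        _, rejected = apply_quality_filters(events)
        reasons = {r.event.event_id: r.rule for r in rejected}
        assert reasons["low_est_es"] == "min_est_skipping"
        assert reasons["dual_as"] == "excluded_class"
        by_id = {e.event_id: e for e in events}
        assert by_id["dual_as"].as_class == "EXCLUDED"  # excluded before filtering
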