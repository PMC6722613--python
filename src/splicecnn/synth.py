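"""Seed-deterministic synthetic genomes and event tables with planted,
class-dependent splice-site structure.

The generator emulates the shape of an EST-derived exon-centric dataset:

* four classes with abundances proportional to a large human exon catalog
  (CON : ES : ALT3 : ALT5 = 39128 : 11590 : 2332 : 2172, scalable);
* bimodal inclusion/usage levels (most alternative events are either >90%
  or <10% included);
* realistic exon (truncated normal, mean 140 nt, min 25) and intron
  (log-normal, median ~1000 nt, min 80) lengths;
* canonical splice-site consensus motifs at every junction — a
  pyrimidine-tract + AG acceptor and a GT-rich donor 7-mer — with
  class-dependent extras: ALT3/ALT5 events carry a secondary
  acceptor/donor at a short offset from the primary site, and cassette
  (ES) exons carry intronic silencer 7-mers in both flanks together with
  weakened primary sites.

Every planted probability matrix is returned in the ground-truth bundle so
motif-recovery tests have an exact target.  EST counts are drawn from
shifted Poisson distributions floored at the quality-filter thresholds, so
default data passes filtering; the adversarial table is the only source of
violators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .events import FilterThresholds, SplicingEvent, classify_events, write_event_table

__all__ = [
    "SynthConfig",
    "SyntheticDataset",
    "generate_dataset",
    "generate_adversarial_table",
    "difficulty_gradient",
    "write_fasta",
    "acceptor_pwm",
    "donor_pwm",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_IDX = {b: i for i, b in enumerate("ACGT")}

ACCEPTOR_CONSENSUS = "YYYYYYYYYYYYAG"  # 12-nt pyrimidine tract + AG (3'ss)
DONOR_CONSENSUS = "GTAAGTT"  # intron start at the 5'ss
SILENCER_UP = "CTCTCTC"  # CU-rich, PTBP1-like
SILENCER_DOWN = "TTTATTT"  # U-rich, TIA1-like

TABLE_RATIOS = {"CON": 39128, "ES": 11590, "ALT3": 2332, "ALT5": 2172}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generator.

    ``scale`` multiplies the reference class abundances; ``motif_strength``
    is the per-position probability of the consensus base; cassette-exon
    primary sites are weakened by ``es_site_factor``.  With
    ``gradient=True``, silencers of highly included (level > 0.8) cassette
    exons are planted at ``gradient_silencer_strength`` instead of
    ``motif_strength``, which makes them statistically closer to
    constitutive exons.
    """

    scale: float = 0.02
    class_counts: dict | None = None  # overrides scale when given
    motif_strength: float = 0.9
    es_site_factor: float = 0.85
    gradient: bool = False
    gradient_silencer_strength: float = 0.55
    secondary_offset_range: tuple[int, int] = (6, 30)
    exon_len_mean: float = 140.0
    exon_len_sd: float = 50.0
    min_exon_len: int = 25
    intron_len_median: float = 1000.0
    intron_len_log_sd: float = 0.6
    min_intron_len: int = 80
    level_beta: tuple[float, float] = (1.0, 9.0)  # low mode; high mode mirrored
    events_per_chrom: int = 1000
    spacer: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.motif_strength <= 1.0:
            raise ValueError("motif_strength must lie in [0.5, 1]")
        lo, hi = self.secondary_offset_range
        if not (0 < lo <= hi <= 40):
            raise ValueError("secondary site offsets must fit inside the 70-nt window")

    def counts(self) -> dict[str, int]:
        if self.class_counts is not None:
            return dict(self.class_counts)
        return {c: max(1, round(n * self.scale)) for c, n in TABLE_RATIOS.items()}


def _consensus_pwm(consensus: str, strength: float) -> np.ndarray:
    """Planted probability matrix: `strength` on the consensus base(s),
    remainder spread over the others; Y splits strength between C and T."""
    pwm = np.zeros((len(consensus), 4))
    for i, ch in enumerate(consensus):
        if ch == "Y":
            pwm[i] = [(1 - strength) / 2, strength / 2, (1 - strength) / 2, strength / 2]
        else:
            pwm[i] = (1 - strength) / 3
            pwm[i, _IDX[ch]] = strength
    return pwm


def acceptor_pwm(strength: float = 0.9) -> np.ndarray:
    return _consensus_pwm(ACCEPTOR_CONSENSUS, strength)


def donor_pwm(strength: float = 0.9) -> np.ndarray:
    return _consensus_pwm(DONOR_CONSENSUS, strength)


def _sample_motif(consensus: str, strength: float, rng: np.random.Generator) -> np.ndarray:
    """One realization of a consensus motif as base indices."""
    out = np.empty(len(consensus), dtype=np.uint8)
    for i, ch in enumerate(consensus):
        if rng.random() < strength:
            out[i] = _IDX[rng.choice(["C", "T"])] if ch == "Y" else _IDX[ch]
        else:
            choices = [0, 1, 2, 3]
            if ch != "Y":
                choices.remove(_IDX[ch])
            out[i] = rng.choice(choices)
    return out


@dataclass
class SyntheticDataset:
    """Generated genome, classified events and the ground-truth bundle."""

    genome: dict[str, str]
    events: list[SplicingEvent]
    truth: dict

    def write(self, fasta_path, tsv_path, truth_path=None) -> None:
        write_fasta(self.genome, fasta_path)
        write_event_table(self.events, tsv_path)
        if truth_path is not None:
            with open(truth_path, "w") as fh:
                json.dump(self.truth, fh, indent=1)


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _draw_levels(n: int, cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Bimodal mixture: half near 0 (Beta(a,b)), half near 1 (Beta(b,a))."""
    a, b = cfg.level_beta
    low = rng.random(n) < 0.5
    lv = np.where(low, rng.beta(a, b, n), rng.beta(b, a, n))
    return np.clip(lv, 1e-3, 1 - 1e-3)


def generate_dataset(cfg: SynthConfig | None = None) -> SyntheticDataset:
    """Generate the genome, the event table and the ground truth.

    Every event carries the primary acceptor/donor consensus at its
    junctions; class-dependent secondary sites and silencers are planted
    inside the 70-nt flanks so they always fall within the extracted
    windows.  Fully reproducible from ``cfg.seed``.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    counts = cfg.counts()
    lo_off, hi_off = cfg.secondary_offset_range

    classes: list[str] = []
    for cls in ("CON", "ES", "ALT3", "ALT5"):
        classes += [cls] * counts[cls]
    order = rng.permutation(len(classes))
    classes = [classes[i] for i in order]

    genome: dict[str, list[np.ndarray]] = {}
    events: list[SplicingEvent] = []
    truth_events: list[dict] = []
    chrom_cursor = 0
    chrom_name = ""
    chrom_parts: list[np.ndarray] = []

    def flush_chrom():
        nonlocal chrom_parts
        if chrom_name:
            genome[chrom_name] = chrom_parts
        chrom_parts = []

    for i, cls in enumerate(classes):
        if i % cfg.events_per_chrom == 0:
            flush_chrom()
            chrom_name = f"chrS{i // cfg.events_per_chrom + 1}"
            chrom_cursor = 0

        l2 = max(cfg.min_exon_len, int(round(rng.normal(cfg.exon_len_mean, cfg.exon_len_sd))))
        l1 = max(cfg.min_intron_len, int(round(rng.lognormal(np.log(cfg.intron_len_median), cfg.intron_len_log_sd))))
        l3 = max(cfg.min_intron_len, int(round(rng.lognormal(np.log(cfg.intron_len_median), cfg.intron_len_log_sd))))
        region = rng.integers(0, 4, size=l1 + l2 + l3, dtype=np.uint8)

        # class-dependent levels and EST support
        incl = u3 = u5 = 1.0
        est_incl = est_excl = est_alt3 = est_alt5 = 0
        if cls == "CON":
            est_incl = 20 + int(rng.poisson(40))
        elif cls == "ES":
            incl = float(_draw_levels(1, cfg, rng)[0])
            total = 20 + int(rng.poisson(30))
            est_incl = int(round(total * incl))
            est_excl = total - est_incl
        elif cls == "ALT3":
            u3 = float(_draw_levels(1, cfg, rng)[0])
            est_incl = 20 + int(rng.poisson(30))
            est_alt3 = 4 + int(rng.poisson(10))
        elif cls == "ALT5":
            u5 = float(_draw_levels(1, cfg, rng)[0])
            est_incl = 20 + int(rng.poisson(30))
            est_alt5 = 4 + int(rng.poisson(10))

        site_strength = cfg.motif_strength * (cfg.es_site_factor if cls == "ES" else 1.0)
        rec: dict = {"class": cls}

        # secondary sites first so the primary consensus is never clobbered
        if cls == "ALT3":
            d = int(rng.integers(lo_off, hi_off + 1))
            start = l1 + d - len(ACCEPTOR_CONSENSUS)
            region[start : l1 + d] = _sample_motif(ACCEPTOR_CONSENSUS, cfg.motif_strength, rng)
            rec["secondary_acceptor_offset"] = d
        if cls == "ALT5":
            d = int(rng.integers(lo_off, hi_off + 1))
            start = l1 + l2 - d
            region[start : start + len(DONOR_CONSENSUS)] = _sample_motif(
                DONOR_CONSENSUS, cfg.motif_strength, rng
            )
            rec["secondary_donor_offset"] = d
        if cls == "ES":
            sil_strength = cfg.motif_strength
            if cfg.gradient and incl > 0.8:
                sil_strength = cfg.gradient_silencer_strength
            up_pos = int(rng.integers(l1 - 68, l1 - 22))  # upstream-intron part of the acceptor window
            region[up_pos : up_pos + 7] = _sample_motif(SILENCER_UP, sil_strength, rng)
            down_pos = int(rng.integers(l1 + l2 + 10, l1 + l2 + 61))  # downstream-intron part of the donor window
            region[down_pos : down_pos + 7] = _sample_motif(SILENCER_DOWN, sil_strength, rng)
            rec["silencer_up_pos"] = up_pos - l1  # relative to acceptor junction
            rec["silencer_down_pos"] = down_pos - (l1 + l2)
            rec["silencer_strength"] = sil_strength

        # primary sites at the junctions
        region[l1 - len(ACCEPTOR_CONSENSUS) : l1] = _sample_motif(
            ACCEPTOR_CONSENSUS, site_strength, rng
        )
        region[l1 + l2 : l1 + l2 + len(DONOR_CONSENSUS)] = _sample_motif(
            DONOR_CONSENSUS, site_strength, rng
        )

        strand = "+" if rng.random() < 0.5 else "-"
        spacer = rng.integers(0, 4, size=cfg.spacer, dtype=np.uint8)
        if strand == "-":
            inserted = (3 - region)[::-1]  # reverse complement of the index array
            exon_start = chrom_cursor + cfg.spacer + l3
        else:
            inserted = region
            exon_start = chrom_cursor + cfg.spacer + l1
        chrom_parts.append(spacer)
        chrom_parts.append(inserted)
        chrom_cursor += cfg.spacer + len(region)

        event_id = f"ev{i:06d}"
        events.append(
            SplicingEvent(
                event_id=event_id,
                chrom=chrom_name,
                strand=strand,
                exon_start=int(exon_start),
                exon_end=int(exon_start + l2),
                upstream_intron_len=l1,
                downstream_intron_len=l3,
                incl_level=incl,
                usage3_level=u3,
                usage5_level=u5,
                est_incl=est_incl,
                est_excl=est_excl,
                est_alt3=est_alt3,
                est_alt5=est_alt5,
            )
        )
        rec["event_id"] = event_id
        rec["strand"] = strand
        truth_events.append(rec)
    flush_chrom()

    genome_str = {
        name: "".join(BASES[np.concatenate(parts)].tobytes().decode()) if parts else ""
        for name, parts in genome.items()
    }
    es_strength = cfg.motif_strength * cfg.es_site_factor
    truth = {
        "config": {
            "scale": cfg.scale,
            "motif_strength": cfg.motif_strength,
            "gradient": cfg.gradient,
            "seed": cfg.seed,
        },
        "class_counts": cfg.counts(),
        "motifs": {
            "acceptor_consensus": ACCEPTOR_CONSENSUS,
            "donor_consensus": DONOR_CONSENSUS,
            "acceptor_pwm": acceptor_pwm(cfg.motif_strength).tolist(),
            "donor_pwm": donor_pwm(cfg.motif_strength).tolist(),
            "es_acceptor_pwm": acceptor_pwm(es_strength).tolist(),
            "es_donor_pwm": donor_pwm(es_strength).tolist(),
            "silencer_up_pwm": _consensus_pwm(SILENCER_UP, cfg.motif_strength).tolist(),
            "silencer_down_pwm": _consensus_pwm(SILENCER_DOWN, cfg.motif_strength).tolist(),
        },
        "events": truth_events,
    }
    return SyntheticDataset(genome=genome_str, events=classify_events(events), truth=truth)


def difficulty_gradient(cfg: SynthConfig | None = None) -> SyntheticDataset:
    """Dataset where silencer strength drops for highly included cassette
    exons, so a trained classifier should separate moderately/rarely
    included exons from constitutive ones more easily than highly included
    ones (the HEvents-vs-MREvents accuracy gap)."""
    cfg = cfg or SynthConfig()
    return generate_dataset(replace(cfg, gradient=True))


def generate_adversarial_table(thresholds: FilterThresholds | None = None) -> tuple[list[SplicingEvent], dict[str, bool]]:
    """A fixed 10-record battery: five clean events and five that each
    violate exactly one quality-filter rule.  Returns the classified events
    and the expected keep/reject outcome per event id."""
    t = thresholds or FilterThresholds()

    def ev(event_id, cls, **kw):
        base = dict(
            event_id=event_id,
            chrom="chrAdv",
            strand="+",
            exon_start=1000,
            exon_end=1120,
            upstream_intron_len=500,
            downstream_intron_len=500,
            incl_level=1.0,
            usage3_level=1.0,
            usage5_level=1.0,
            est_incl=50,
            est_excl=0,
            est_alt3=0,
            est_alt5=0,
        )
        if cls == "ES":
            base.update(incl_level=0.5, est_incl=15, est_excl=15)
        elif cls == "ALT3":
            base.update(usage3_level=0.5, est_alt3=10)
        elif cls == "ALT5":
            base.update(usage5_level=0.5, est_alt5=10)
        base.update(kw)
        return SplicingEvent(**base)

    records = [
        (ev("clean_con", "CON"), True),
        (ev("clean_es", "ES"), True),
        (ev("clean_alt3", "ALT3"), True),
        (ev("clean_alt5", "ALT5"), True),
        (ev("clean_es2", "ES", incl_level=0.9, est_incl=90, est_excl=10), True),
        # one violator per rule
        (ev("low_est_es", "ES", est_incl=10, est_excl=9), False),  # 19 < min_est_skipping
        (ev("low_est_alt3", "ALT3", est_alt3=t.min_est_altsite - 1), False),
        (ev("short_exon", "CON", exon_end=1000 + t.min_exon_len - 1), False),
        (ev("short_intron", "CON", upstream_intron_len=t.min_intron_len - 1), False),
        (ev("dual_as", "CON", usage3_level=0.7, usage5_level=0.6), False),  # EXCLUDED class
    ]
    events = classify_events([r[0] for r in records])
    expected = {r[0].event_id: r[1] for r in records}
    return events, expected
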