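"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure of a large curated
karyotype registry: per-class aberration frequency profiles,
heavy-tailed aberration counts per karyotype (independent Bernoulli
events whose latent block-activation bursts overdisperse the count
distribution into a geometric-like tail), planted gain-gain/loss-loss
co-occurrence blocks, multiclonal cases, and contaminating records
(selected-flagged, unparsable, non-near-diploid).  ISCN strings are
rendered from the sampled events so the parser and reconstructor are
exercised end to end, and every record's true event set is emitted
alongside.

Co-occurrence is planted through a latent block-activation indicator:
each karyotype flips one coin per block (probability ``activation_prob``);
when active, every member's inclusion probability is multiplied by
``multiplier``; when inactive it is lowered so the marginal frequency
stays at the configured base value.  The joint distribution is therefore
analytically known, and ``multiplier=1`` recovers exact independence
(the type-I-control condition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .aberrations import GAIN, LOSS, Aberration, parse_canonical
from .bands import CHROMOSOMES
from .iscn import render_iscn

AUTOSOMES = tuple(str(i) for i in range(1, 23))


@dataclass(frozen=True)
class ClassSpec:
    name: str
    category: str
    size: int


@dataclass(frozen=True)
class BlockSpec:
    """A planted co-occurrence block over canonical aberration ids."""

    members: tuple[str, ...]
    multiplier: float = 1.0
    activation_prob: float = 1.0 / 6.0

    def probabilities(self, base: float) -> tuple[float, float]:
        """(active, inactive) member inclusion probabilities for base freq."""
        p_hi = base * self.multiplier
        pi = self.activation_prob
        p_lo = base * (1 - pi * self.multiplier) / (1 - pi) if pi < 1 else p_hi
        return p_hi, p_lo

    def validate(self, base_freqs: dict[str, float]) -> None:
        if self.multiplier < 1:
            raise ValueError("block multiplier must be >= 1")
        if not (0 < self.activation_prob < 1) and self.multiplier != 1:
            raise ValueError("activation probability must lie in (0, 1)")
        for member in self.members:
            base = base_freqs.get(member, 0.0)
            p_hi, p_lo = self.probabilities(base)
            if p_hi > 1 or p_lo < 0:
                raise ValueError(
                    f"infeasible block parameters for {member}: "
                    f"active={p_hi:.3f}, inactive={p_lo:.3f}"
                )


@dataclass
class CohortConfig:
    """Study conditions for one synthetic karyotype cohort."""

    classes: list[ClassSpec]
    # per-class base frequency of each canonical aberration id
    aberration_pool: dict[str, dict[str, float]]
    gain_block: BlockSpec | None = None
    loss_block: BlockSpec | None = None
    # rare independent background aberrations (one Bernoulli coin each;
    # independence keeps the null condition free of planted structure)
    background_pool: tuple[str, ...] = ()
    background_freq: float = 0.05
    contamination: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for cls in self.classes:
            if cls.size < 0:
                raise ValueError("class size must be non-negative")
            for ab, f in self.aberration_pool.get(cls.name, {}).items():
                if not 0 <= f <= 1:
                    raise ValueError(f"frequency out of range for {ab}: {f}")
        for frac in self.contamination.values():
            if not 0 <= frac <= 1:
                raise ValueError("contamination fractions must lie in [0, 1]")
        if not 0 <= self.background_freq <= 1:
            raise ValueError("background frequency must lie in [0, 1]")
        for block in (self.gain_block, self.loss_block):
            if block is None:
                continue
            for cls in self.classes:
                block.validate(self.aberration_pool.get(cls.name, {}))


def _sample_karyotype(
    rng: np.random.Generator, config: CohortConfig, class_name: str
) -> tuple[list[Aberration], bool, bool]:
    freqs = config.aberration_pool.get(class_name, {})
    gain_active = bool(
        config.gain_block and rng.random() < config.gain_block.activation_prob
    )
    loss_active = bool(
        config.loss_block and rng.random() < config.loss_block.activation_prob
    )
    chosen: list[str] = []
    for ab, base in freqs.items():
        prob = base
        for block, active in (
            (config.gain_block, gain_active),
            (config.loss_block, loss_active),
        ):
            if block and ab in block.members:
                p_hi, p_lo = block.probabilities(base)
                prob = p_hi if active else p_lo
        if rng.random() < prob:
            chosen.append(ab)
    for ab in config.background_pool:
        if ab not in chosen and rng.random() < config.background_freq:
            chosen.append(ab)
    events = [parse_canonical(ab) for ab in sorted(set(chosen))]
    return events, gain_active, loss_active


def _record(
    rng: np.random.Generator,
    events: list[Aberration],
    record_id: str,
    case_id: str,
    clone_index: int,
    class_name: str,
    category: str,
    selected: int = 0,
) -> dict:
    gains = sum(1 for e in events if e.kind == GAIN)
    losses = sum(1 for e in events if e.kind == LOSS)
    modal = 46 + gains - losses
    sex = "XX" if rng.random() < 0.5 else "XY"
    return {
        "record_id": record_id,
        "case_id": case_id,
        "clone_index": clone_index,
        "iscn": render_iscn(modal, sex, events),
        "tumor_class": class_name,
        "category": category,
        "selected": selected,
    }


def generate_cohort(
    config: CohortConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (records, truth) frames; a pure function of (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: list[dict] = []
    truth: list[dict] = []
    counter = 0

    def next_ids():
        nonlocal counter
        counter += 1
        return f"R{counter:05d}", f"C{counter:05d}"

    def emit(class_name, category, contaminant="", selected=0):
        rid, cid = next_ids()
        events, g_act, l_act = _sample_karyotype(rng, config, class_name)
        records.append(
            _record(rng, events, rid, cid, 0, class_name, category, selected)
        )
        truth.append(
            {
                "record_id": rid,
                "true_events": "|".join(e.canonical_id for e in events),
                "gain_block_active": int(g_act),
                "loss_block_active": int(l_act),
                "contaminant": contaminant,
            }
        )
        return rid, cid

    for cls in config.classes:
        for _ in range(cls.size):
            emit(cls.name, cls.category)

    n_core = counter
    frac = config.contamination.get

    # selected-flagged records (excluded by the first filter stage)
    for _ in range(round(frac("selected", 0.0) * n_core)):
        cls = config.classes[int(rng.integers(len(config.classes)))]
        rid, cid = next_ids()
        events, *_ = _sample_karyotype(rng, config, cls.name)
        records.append(
            _record(rng, events, rid, cid, 0, cls.name, cls.category, selected=1)
        )
        truth.append(
            {
                "record_id": rid,
                "true_events": "",
                "gain_block_active": 0,
                "loss_block_active": 0,
                "contaminant": "selected",
            }
        )

    # unparsable / partially characterised records
    bad_iscn = ["4x,XX,+8", "46,XX,?inv(3)", "46,XY,mar", "47,XX,add(5),+8"]
    for k in range(round(frac("invalid", 0.0) * n_core)):
        cls = config.classes[int(rng.integers(len(config.classes)))]
        rid, cid = next_ids()
        records.append(
            {
                "record_id": rid,
                "case_id": cid,
                "clone_index": 0,
                "iscn": bad_iscn[k % len(bad_iscn)],
                "tumor_class": cls.name,
                "category": cls.category,
                "selected": 0,
            }
        )
        truth.append(
            {
                "record_id": rid,
                "true_events": "",
                "gain_block_active": 0,
                "loss_block_active": 0,
                "contaminant": "invalid",
            }
        )

    # valid but not near-diploid records (12 gains or 12 losses)
    for k in range(round(frac("non_near_diploid", 0.0) * n_core)):
        cls = config.classes[int(rng.integers(len(config.classes)))]
        rid, cid = next_ids()
        chroms = rng.choice(22, size=12, replace=False) + 1
        kind = GAIN if k % 2 == 0 else LOSS
        events = [Aberration(kind, (str(c),)) for c in chroms]
        records.append(_record(rng, events, rid, cid, 0, cls.name, cls.category))
        truth.append(
            {
                "record_id": rid,
                "true_events": "|".join(e.canonical_id for e in events),
                "gain_block_active": 0,
                "loss_block_active": 0,
                "contaminant": "non_near_diploid",
            }
        )

    # multiclonal cases: an extra clone appended to an existing case
    n_multi = round(frac("multiclonal", 0.0) * n_core)
    if n_multi:
        host_idx = rng.choice(n_core, size=n_multi, replace=False)
        for idx in host_idx:
            host = records[int(idx)]
            counter += 1
            rid = f"R{counter:05d}"
            events, *_ = _sample_karyotype(rng, config, host["tumor_class"])
            records.append(
                _record(
                    rng,
                    events,
                    rid,
                    host["case_id"],
                    1,
                    host["tumor_class"],
                    host["category"],
                )
            )
            truth.append(
                {
                    "record_id": rid,
                    "true_events": "",
                    "gain_block_active": 0,
                    "loss_block_active": 0,
                    "contaminant": "multiclonal",
                }
            )

    return pd.DataFrame(records), pd.DataFrame(truth)


@dataclass
class CGHConfig:
    """Study conditions for a synthetic CGH segment cohort."""

    n_samples: int = 400
    # base marginal frequency of each planted whole-chromosome call
    call_freqs: dict[str, float] = field(default_factory=dict)
    gain_block: BlockSpec | None = None
    loss_block: BlockSpec | None = None
    arm_internal_rate: float = 1.0  # mean decoy segments per sample (Poisson)
    seed: int = 0

    def validate(self) -> None:
        for ab, f in self.call_freqs.items():
            if not 0 <= f <= 1:
                raise ValueError(f"frequency out of range for {ab}: {f}")
        for block in (self.gain_block, self.loss_block):
            if block is not None:
                block.validate(self.call_freqs)


def generate_cgh(
    config: CGHConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (segments, truth) frames for the CGH validation arm.

    Every planted whole-chromosome call becomes one centromere-spanning
    segment; decoy segments internal to one arm are added at the
    configured Poisson rate and must not be called.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p_bands = ["p15", "p14", "p13", "p12", "p11"]
    q_bands = ["q11", "q12", "q13", "q21", "q22", "q23", "q24"]
    seg_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    for s in range(config.n_samples):
        sample_id = f"S{s + 1:04d}"
        gain_active = bool(
            config.gain_block and rng.random() < config.gain_block.activation_prob
        )
        loss_active = bool(
            config.loss_block and rng.random() < config.loss_block.activation_prob
        )
        calls = []
        for ab, base in config.call_freqs.items():
            prob = base
            for block, active in (
                (config.gain_block, gain_active),
                (config.loss_block, loss_active),
            ):
                if block and ab in block.members:
                    p_hi, p_lo = block.probabilities(base)
                    prob = p_hi if active else p_lo
            if rng.random() < prob:
                calls.append(ab)
        for ab in sorted(calls):
            chrom = ab[1:]
            direction = "gain" if ab[0] == "+" else "loss"
            start = p_bands[int(rng.integers(len(p_bands)))]
            end = q_bands[int(rng.integers(len(q_bands)))]
            seg_rows.append((sample_id, chrom, start, end, direction))
        for _ in range(rng.poisson(config.arm_internal_rate)):
            chrom = CHROMOSOMES[int(rng.integers(len(CHROMOSOMES)))]
            bands = p_bands if rng.random() < 0.5 else q_bands
            i, j = sorted(rng.choice(len(bands), size=2, replace=False))
            direction = "gain" if rng.random() < 0.5 else "loss"
            seg_rows.append((sample_id, chrom, bands[i], bands[j], direction))
        truth_rows.append((sample_id, "|".join(sorted(calls))))
    segments = pd.DataFrame(
        seg_rows,
        columns=["sample_id", "chromosome", "start_band", "end_band", "direction"],
    )
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "true_calls"])
    return segments, truth


@dataclass
class MMConfig:
    """Study conditions for the synthetic multiple-myeloma cohort."""

    n: int = 385
    hyperdiploid_fraction: float = 0.29
    preference: tuple[int, ...] = (9, 15, 19)
    preference_gain_prob: float = 0.8
    other_gain_prob: float = 0.06
    # non-hyperdiploid records: probability of carrying one stray trisomy,
    # and the odds weight tilting that trisomy toward the preference set
    nonhyper_gain_prob: float = 0.25
    nonhyper_preference_weight: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.hyperdiploid_fraction <= 1:
            raise ValueError("hyperdiploid fraction must lie in [0, 1]")
        for p in (self.preference_gain_prob, self.other_gain_prob):
            if not 0 <= p <= 1:
                raise ValueError("gain probabilities must lie in [0, 1]")


def generate_mm_cohort(
    config: MMConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (records, truth) for the trisomy-index analysis.

    Hyperdiploid records get modal counts in 48-74 with elevated gain
    probability on the preference chromosomes; the rest stay at 35-47
    with background gains/losses.  Truth carries the H-MM label.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: list[dict] = []
    truth_rows: list[tuple] = []
    for i in range(config.n):
        rid = f"MM{i + 1:04d}"
        hyper = rng.random() < config.hyperdiploid_fraction
        gains: set[int] = set()
        losses: set[int] = set()
        if hyper:
            for c in range(1, 23):
                p = (
                    config.preference_gain_prob
                    if c in config.preference
                    else config.other_gain_prob
                )
                if rng.random() < p:
                    gains.add(c)
            while len(gains) < 2:  # hyperdiploidy requires modal >= 48
                gains.add(int(rng.integers(1, 23)))
        else:
            if rng.random() < config.nonhyper_gain_prob:
                weights = np.array(
                    [
                        config.nonhyper_preference_weight
                        if c in config.preference
                        else 1.0
                        for c in range(1, 23)
                    ]
                )
                gains.add(int(rng.choice(np.arange(1, 23), p=weights / weights.sum())))
            n_loss = int(rng.binomial(3, 0.3))
            while len(losses) < n_loss:
                c = int(rng.integers(1, 23))
                if c not in gains:
                    losses.add(c)
        events = [Aberration(GAIN, (str(c),)) for c in sorted(gains)] + [
            Aberration(LOSS, (str(c),)) for c in sorted(losses)
        ]
        records.append(
            _record(rng, events, rid, rid, 0, "MM", "lymphoid", selected=0)
        )
        truth_rows.append((rid, int(hyper)))
    truth = pd.DataFrame(truth_rows, columns=["record_id", "hmm"])
    return pd.DataFrame(records), truth


# -- shipped default study conditions ---------------------------------------

GAIN_BLOCK_MEMBERS = ("+3", "+5", "+7", "+8", "+9", "+11", "+15", "+19")
LOSS_BLOCK_MEMBERS = ("-6", "-10", "-13", "-17", "-18")


def default_cohort_config(
    seed: int = 0, multiplier: float = 6.0, activation_prob: float = 1.0 / 6.0
) -> CohortConfig:
    """The shipped default synthetic cohort: 1,200 karyotypes, 6 classes,
    one planted gain block (8 members) and one loss block (5 members),
    class-specific structural aberrations and contamination records.
    """
    gain_freq = {ab: 0.08 for ab in GAIN_BLOCK_MEMBERS}
    loss_freq = {ab: 0.07 for ab in LOSS_BLOCK_MEMBERS}
    base = {**gain_freq, **loss_freq}
    pool = {
        "LYM-A": {**base, "t(8;14)(q24;q32)": 0.14, "t(14;18)(q32;q21)": 0.08},
        "LYM-B": {**base, "t(9;22)(q34;q11)": 0.10, "del(6)(q21)": 0.06},
        "NLH-A": {**base, "t(9;22)(q34;q11)": 0.18, "i(17)(q10)": 0.05},
        "NLH-B": {**base, "del(5)(q13q33)": 0.12, "inv(3)(p21q26)": 0.04},
        "SOL-M": {**base, "t(11;22)(q24;q12)": 0.12, "dup(1)(q21q32)": 0.05},
        "SOL-B": {**base, "del(7)(q22q32)": 0.06, "inv(12)(p11q13)": 0.04},
    }
    classes = [
        ClassSpec("LYM-A", "lymphoid", 260),
        ClassSpec("LYM-B", "lymphoid", 180),
        ClassSpec("NLH-A", "non-lymphoid hematological", 300),
        ClassSpec("NLH-B", "non-lymphoid hematological", 200),
        ClassSpec("SOL-M", "malignant solid", 160),
        ClassSpec("SOL-B", "benign solid", 100),
    ]
    return CohortConfig(
        classes=classes,
        aberration_pool=pool,
        gain_block=BlockSpec(GAIN_BLOCK_MEMBERS, multiplier, activation_prob),
        loss_block=BlockSpec(LOSS_BLOCK_MEMBERS, multiplier, activation_prob),
        background_pool=("t(1;3)(p11;q21)", "del(11)(q23)", "dup(3)(q21q26)"),
        contamination={
            "selected": 0.08,
            "invalid": 0.05,
            "non_near_diploid": 0.04,
            "multiclonal": 0.05,
        },
        seed=seed,
    )


def default_cgh_config(
    seed: int = 0, multiplier: float = 4.0, activation_prob: float = 0.2
) -> CGHConfig:
    gains = ("+1", "+2", "+3", "+7", "+8")
    losses = ("-16", "-17", "-18")
    freqs = {ab: 0.15 for ab in gains} | {ab: 0.12 for ab in losses}
    return CGHConfig(
        n_samples=400,
        call_freqs=freqs,
        gain_block=BlockSpec(gains, multiplier, activation_prob),
        loss_block=BlockSpec(losses, multiplier, activation_prob),
        arm_internal_rate=1.2,
        seed=seed,
    )


def three_group_config(seed: int = 0) -> CohortConfig:
    """Nine classes in three groups with group-private aberration profiles.

    Each group owns eight structural aberrations present at frequency
    0.25 in its three member classes and absent elsewhere, so the
    correlative matrix M_t is block-structured: class-similarity
    significance should fall within groups only and the three-cluster
    dendrogram cut should recover the groups.
    """
    group_events = {
        "G1": (
            "t(8;14)(q24;q32)",
            "t(14;18)(q32;q21)",
            "t(2;8)(p12;q24)",
            "del(6)(q21)",
            "del(13)(q14)",
            "dup(1)(q21q32)",
            "t(11;14)(q13;q32)",
            "del(11)(q23)",
        ),
        "G2": (
            "t(9;22)(q34;q11)",
            "t(8;21)(q22;q22)",
            "inv(16)(p13q22)",
            "del(5)(q13q33)",
            "del(7)(q22q32)",
            "i(17)(q10)",
            "t(15;17)(q22;q21)",
            "del(20)(q11q13)",
        ),
        "G3": (
            "t(11;22)(q24;q12)",
            "t(12;16)(q13;p11)",
            "t(2;13)(q35;q14)",
            "del(1)(p36)",
            "del(3)(p14p23)",
            "dup(12)(q13q15)",
            "i(12)(p10)",
            "del(9)(p21)",
        ),
    }
    categories = {
        "G1": "lymphoid",
        "G2": "non-lymphoid hematological",
        "G3": "malignant solid",
    }
    common = {f"+{c}": 0.04 for c in (8, 12, 21)}
    classes, pool = [], {}
    for group, events in group_events.items():
        for k in range(3):
            name = f"{group}-{k + 1}"
            classes.append(ClassSpec(name, categories[group], 120))
            pool[name] = {**common, **{ab: 0.25 for ab in events}}
    return CohortConfig(
        classes=classes, aberration_pool=pool, contamination={}, seed=seed
    )


def load_config(path: str) -> CohortConfig:
    """Read a CohortConfig from a YAML file (flat key-value structure)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    classes = [ClassSpec(**c) for c in raw["classes"]]
    blocks = {}
    for key in ("gain_block", "loss_block"):
        if raw.get(key):
            spec = dict(raw[key])
            spec["members"] = tuple(spec["members"])
            blocks[key] = BlockSpec(**spec)
        else:
            blocks[key] = None
    return CohortConfig(
        classes=classes,
        aberration_pool=raw["aberration_pool"],
        gain_block=blocks["gain_block"],
        loss_block=blocks["loss_block"],
        background_pool=tuple(raw.get("background_pool", ())),
        background_freq=raw.get("background_freq", 0.05),
        contamination=raw.get("contamination", {}),
        seed=raw.get("seed", 0),
    )
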