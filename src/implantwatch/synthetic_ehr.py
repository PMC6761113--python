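"""Fully synthetic EHR generator with planted ground truth.

Every pipeline stage is testable without access to real clinical data:
the generator emits templated clinical notes (with section headers,
inline dates, and negated/historical/hypothetical variants of relation
sentences), coded procedure records, demographics, a registry snapshot,
and simulated survival/count outcomes, all as pure functions of
(config, seed).

What it emulates: the statistical structure the downstream analyses
assume — implant systems drawn from a frequency table, revision hazards
that are multiplicative per system, pain-mention counts that are negative
binomial with per-system rate ratios, and clinical language in which a
substantial fraction of mentions are negated, historical, or
hypothetical. What it does not emulate: real clinical style, laterality,
coreference, or vocabulary beyond the template/lexicon inventory.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources as _ilres
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .corpus_io import CodedRecord, Corpus, Demographics, Note, PatientRecord
from .events import RegistryRecord

__all__ = [
    "SimConfig",
    "GoldEntity",
    "GoldRelation",
    "GroundTruth",
    "load_templates",
    "simulate_corpus",
    "simulate_votes",
    "simulate_survival",
    "simulate_counts",
]

# (acetabular surface, femoral surface) -> sampling probability. The
# reference system (Trilogy + VerSys) is the most frequent, mirroring the
# mix of Zimmer Biomet and Depuy families a large orthopaedic service uses.
DEFAULT_SYSTEM_TABLE: dict[tuple[str, str], float] = {
    ("Zimmer Biomet Trilogy", "Zimmer Biomet VerSys"): 0.30,
    ("Depuy Pinnacle", "Depuy Corail"): 0.12,
    ("Depuy Pinnacle", "Depuy Summit"): 0.12,
    ("Zimmer Biomet Trilogy", "Zimmer Biomet M/L Taper"): 0.10,
    ("Zimmer Biomet Continuum", "Zimmer Biomet M/L Taper"): 0.06,
    ("Depuy Pinnacle", "Depuy AML"): 0.06,
    ("Depuy Duraloc", "Depuy AML"): 0.06,
    ("Depuy Duraloc", "Depuy Corail"): 0.05,
    ("Depuy Duraloc", "Depuy Summit"): 0.04,
    ("Depuy Pinnacle", "Depuy Endurance"): 0.04,
    ("Zimmer Biomet Ranawat/Burstein", "Zimmer Biomet Taperloc"): 0.03,
    ("Zimmer Biomet RingLoc", "Zimmer Biomet Taperloc"): 0.02,
}

_COMPLICATION_SURFACES = {
    "revision": ("revision surgery", "component exchange"),
    "component_wear": ("liner wear", "polyethylene wear"),
    "mechanical_failure": ("aseptic loosening", "dislocation"),
    "particle_disease": ("osteolysis", "metallosis"),
    "radiographic_abnormality": ("radiolucency", "subsidence"),
    "infection": ("periprosthetic infection", "deep infection"),
}
_PAIN_SURFACES = ("pain", "tenderness", "aching", "discomfort")
_HIP_ANATOMY = ("left hip", "right hip")
_OTHER_ANATOMY = ("groin", "thigh", "knee")
_RACES = ("white", "black", "asian", "other")
_RACE_P = (0.6, 0.1, 0.2, 0.1)
_ETHNICITIES = ("non-hispanic", "hispanic", "unknown")
_ETH_P = (0.75, 0.15, 0.10)


@dataclass
class SimConfig:
    """Study conditions for the synthetic EHR.

    Defaults are desk-scale but structurally faithful: ~5% of patients
    have a revision within follow-up, follow-up averages ~5.3 years, mean
    hip-pain mentions ~3/year, and a bit over half of relation mentions
    are present-positive with the remainder split across negated,
    historical, and hypothetical variants.
    """

    n_patients: int = 100
    seed: int = 7
    notes_per_patient_mean: float = 3.0  # distractor notes beyond event notes
    variant_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "positive": 0.45,
            "negated": 0.25,
            "historical": 0.20,
            "hypothetical": 0.10,
        }
    )
    system_table: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_SYSTEM_TABLE)
    )
    # label-model truth for simulate_votes
    lf_accuracies: tuple[float, ...] = (0.9, 0.8, 0.75, 0.7, 0.6)
    lf_propensities: tuple[float, ...] = (0.8, 0.8, 0.8, 0.8, 0.8)
    class_prior: float = 0.5
    # survival truth
    baseline_hazard: float = 0.012  # revisions / person-year for the reference
    log_hazard_ratios: Mapping[str, float] = field(default_factory=dict)
    follow_up_range: tuple[float, float] = (1.0, 9.6)  # years, mean ~5.3
    # count truth
    pain_mean: float = 3.23  # mentions / post-op year, reference system
    nb_dispersion: float = 1.5  # NB size k; var = mu + mu^2 / k
    log_irrs: Mapping[str, float] = field(default_factory=dict)
    prior_pain_mean: float = 3.0
    p_coded_revision: float = 0.15  # coded channel sensitivity
    p_text_revision: float = 0.95  # text channel sensitivity

    def __post_init__(self):
        if abs(sum(self.variant_probs.values()) - 1.0) > 1e-9:
            raise ValueError("variant probabilities must sum to 1")
        total = sum(self.system_table.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("system table probabilities must sum to 1")


@dataclass(frozen=True)
class GoldEntity:
    note_id: str
    char_span: tuple[int, int]
    entity_type: str
    surface: str


@dataclass(frozen=True)
class GoldRelation:
    note_id: str
    relation_type: str
    a_span: tuple[int, int]  # pain / complication
    b_span: tuple[int, int]  # anatomy / implant
    variant: str  # positive | negated | historical | hypothetical

    @property
    def key(self) -> tuple:
        return (self.note_id, self.a_span, self.b_span)

    @property
    def is_positive(self) -> bool:
        return self.variant == "positive"


@dataclass
class GroundTruth:
    entities: list[GoldEntity] = field(default_factory=list)
    relations: list[GoldRelation] = field(default_factory=list)
    systems: dict[str, str] = field(default_factory=dict)  # pid -> label
    true_events: list[tuple[str, str, dt.date]] = field(default_factory=list)
    covariates: pd.DataFrame | None = None
    registry: list[RegistryRecord] = field(default_factory=list)


_TEMPLATES_CACHE: dict | None = None


def load_templates() -> dict:
    global _TEMPLATES_CACHE
    if _TEMPLATES_CACHE is None:
        raw = _ilres.files("implantwatch.resources").joinpath("templates.yaml").read_text()
        _TEMPLATES_CACHE = yaml.safe_load(raw)
    return _TEMPLATES_CACHE


def _fill(template: str, values: Mapping[str, str], base: int) -> tuple[str, dict[str, tuple[int, int]]]:
    """Substitute {slot} markers, recording the char span of each filled slot
    relative to ``base`` + local offset."""
    out = []
    spans: dict[str, tuple[int, int]] = {}
    cursor = 0
    pos = 0
    while True:
        i = template.find("{", pos)
        if i < 0:
            out.append(template[pos:])
            break
        j = template.index("}", i)
        out.append(template[pos:i])
        cursor = sum(len(s) for s in out)
        slot = template[i + 1 : j]
        value = values[slot]
        spans[slot] = (base + cursor, base + cursor + len(value))
        out.append(value)
        pos = j + 1
    return "".join(out), spans


class _NoteBuilder:
    def __init__(self, note_id: str):
        self.note_id = note_id
        self.parts: list[str] = []
        self.length = 0

    def add(self, text: str) -> int:
        """Append text, returning the char offset at which it starts."""
        start = self.length
        self.parts.append(text)
        self.length += len(text)
        return start

    def text(self) -> str:
        return "".join(self.parts)


def _sample_system(rng: np.random.Generator, table) -> tuple[str, str]:
    keys = list(table.keys())
    probs = np.array([table[k] for k in keys])
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _system_label(ace: str, fem: str) -> str:
    # "Zimmer Biomet Trilogy" + "Zimmer Biomet VerSys" -> "Zimmer Biomet Trilogy + VerSys"
    fem_model = fem.replace("Zimmer Biomet ", "").replace("Depuy ", "")
    return f"{ace} + {fem_model}"


def _draw_nb(rng: np.random.Generator, mean: float, k: float, size: int) -> np.ndarray:
    """Negative binomial via Gamma-Poisson mixture; k -> inf is Poisson."""
    if not np.isfinite(k):
        return rng.poisson(mean, size=size)
    lam = rng.gamma(shape=k, scale=mean / k, size=size)
    return rng.poisson(lam)


def _relation_sentence(
    rng: np.random.Generator,
    builder: _NoteBuilder,
    gt: GroundTruth,
    relation_type: str,
    variant: str,
    values: Mapping[str, str],
    templates: dict,
) -> None:
    choices = templates[relation_type][variant]
    template = choices[rng.integers(len(choices))]
    if "{old_date}" in template and "old_date" not in values:
        created = getattr(builder, "_created", dt.date(2006, 6, 1))
        values = dict(values)
        values["old_date"] = f"{created.month}/{created.day}/{created.year - 5}"
    text, spans = _fill(template, values, builder.length)
    builder.add(text + "\n")
    a_slot = "pain" if relation_type == "pain_anatomy" else "complication"
    b_slot = "anatomy" if relation_type == "pain_anatomy" else "implant"
    a_type, b_type = (
        ("pain", "anatomy") if relation_type == "pain_anatomy" else ("complication", "implant")
    )
    gt.entities.append(GoldEntity(builder.note_id, spans[a_slot], a_type, values[a_slot]))
    gt.entities.append(GoldEntity(builder.note_id, spans[b_slot], b_type, values[b_slot]))
    gt.relations.append(
        GoldRelation(builder.note_id, relation_type, spans[a_slot], spans[b_slot], variant)
    )


def _choose_variant(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    names = list(probs)
    return names[rng.choice(len(names), p=np.array([probs[n] for n in names]))]


def simulate_corpus(config: SimConfig) -> tuple[Corpus, GroundTruth]:
    """Generate the full synthetic EHR: notes, codes, demographics, registry.

    Deterministic per (config, seed). Gold spans are recorded at note
    construction, so every gold span substring-matches its note text by
    construction (and tests verify it).
    """
    rng = np.random.default_rng(config.seed)
    templates = load_templates()
    corpus: Corpus = {}
    gt = GroundTruth()
    rows = []

    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        ace, fem = _sample_system(rng, config.system_table)
        label = _system_label(ace, fem)
        index_date = dt.date(2000, 1, 1) + dt.timedelta(days=int(rng.integers(0, 3653)))
        age = float(np.clip(rng.normal(63, 10), 30, 90))
        gender = "F" if rng.random() < 0.556 else "M"
        race = _RACES[rng.choice(len(_RACES), p=_RACE_P)]
        ethnicity = _ETHNICITIES[rng.choice(len(_ETHNICITIES), p=_ETH_P)]
        cci = int(rng.poisson(0.8))
        follow_up = float(rng.uniform(*config.follow_up_range))
        birth = index_date - dt.timedelta(days=int(age * 365.25))

        rec = PatientRecord(
            pid, Demographics(birth, gender, race, ethnicity), index_date=index_date
        )
        rec.coded.append(CodedRecord(pid, "ICD9-proc", "81.51", index_date))
        note_seq = 0

        def new_note(day_offset: int, note_class: str = "clinical_note") -> _NoteBuilder:
            nonlocal note_seq
            nid = f"{pid}-N{note_seq:03d}"
            note_seq += 1
            b = _NoteBuilder(nid)
            b._created = index_date + dt.timedelta(days=day_offset)  # type: ignore[attr-defined]
            b._class = note_class  # type: ignore[attr-defined]
            return b

        def close(b: _NoteBuilder) -> None:
            rec.notes.append(
                Note(
                    pid,
                    b.note_id,
                    dt.datetime.combine(b._created, dt.time(12, 0)),
                    b.text(),
                    b._class,
                )
            )

        # --- operative report on the index date -------------------------
        op = new_note(0, "operative_report")
        op.add("OPERATIVE FINDINGS:\n")
        op_templates = templates["operative"]
        text, spans = _fill(
            op_templates[rng.integers(len(op_templates))],
            {"ace_surface": ace, "fem_surface": fem},
            op.length,
        )
        op.add(text + "\n")
        gt.entities.append(GoldEntity(op.note_id, spans["ace_surface"], "implant", ace))
        gt.entities.append(GoldEntity(op.note_id, spans["fem_surface"], "implant", fem))
        close(op)

        # --- revision outcome (exponential, per-system multiplicative) --
        hr = float(np.exp(config.log_hazard_ratios.get(label, 0.0)))
        t_event = float(rng.exponential(1.0 / max(config.baseline_hazard * hr, 1e-12)))
        had_revision = t_event < follow_up
        time_to_revision = min(t_event, follow_up)
        revision_date = index_date + dt.timedelta(days=int(time_to_revision * 365.25))
        if had_revision:
            gt.true_events.append((pid, "revision", revision_date))
            if rng.random() < config.p_coded_revision:
                rec.coded.append(CodedRecord(pid, "CPT", "27134", revision_date))
            if rng.random() < config.p_text_revision:
                b = new_note(int(time_to_revision * 365.25) + int(rng.integers(0, 15)))
                b.add("IMAGING:\n")
                _relation_sentence(
                    rng, b, gt, "implant_complication", "positive",
                    {
                        "complication": _COMPLICATION_SURFACES["revision"][
                            rng.integers(2)
                        ],
                        "implant": ace if rng.random() < 0.5 else fem,
                    },
                    templates,
                )
                close(b)

        # --- pain mentions: NB counts realised as one note per mention --
        mu_post = config.pain_mean * float(np.exp(config.log_irrs.get(label, 0.0)))
        pain_post = int(_draw_nb(rng, mu_post, config.nb_dispersion, 1)[0])
        pain_prior = int(_draw_nb(rng, config.prior_pain_mean, config.nb_dispersion, 1)[0])
        for n_mentions, (lo, hi) in (
            (pain_post, (0, min(365, int(follow_up * 365.25)))),
            (pain_prior, (-365, 0)),
        ):
            for _ in range(n_mentions):
                b = new_note(int(rng.integers(lo, max(hi, lo + 1))))
                b.add("HISTORY OF PRESENT ILLNESS:\n")
                _relation_sentence(
                    rng, b, gt, "pain_anatomy", "positive",
                    {
                        "pain": _PAIN_SURFACES[rng.integers(len(_PAIN_SURFACES))],
                        "anatomy": _HIP_ANATOMY[rng.integers(2)],
                    },
                    templates,
                )
                close(b)

        # --- distractor notes with mixed variants ------------------------
        n_extra = int(rng.poisson(config.notes_per_patient_mean))
        for _ in range(n_extra):
            b = new_note(int(rng.integers(-365, int(follow_up * 365.25) + 1)))
            variant = _choose_variant(rng, config.variant_probs)
            rel = "pain_anatomy" if rng.random() < 0.5 else "implant_complication"
            section = "PAST MEDICAL HISTORY:\n" if variant == "historical" and rng.random() < 0.5 else (
                "IMAGING:\n" if rel == "implant_complication" else "HISTORY OF PRESENT ILLNESS:\n"
            )
            b.add(section)
            filler = templates["filler"]
            b.add(filler[rng.integers(len(filler))] + "\n")
            if rel == "pain_anatomy":
                # distractor pain is non-hip, so it never enters the
                # hip-pain counting windows regardless of its date
                values = {
                    "pain": _PAIN_SURFACES[rng.integers(len(_PAIN_SURFACES))],
                    "anatomy": _OTHER_ANATOMY[rng.integers(len(_OTHER_ANATOMY))],
                }
            else:
                subclass = list(_COMPLICATION_SURFACES)[1 + rng.integers(5)]
                values = {
                    "complication": _COMPLICATION_SURFACES[subclass][rng.integers(2)],
                    "implant": ace if rng.random() < 0.5 else fem,
                }
            if section.startswith("PAST"):
                variant = "historical"
            _relation_sentence(rng, b, gt, rel, variant, values, templates)
            close(b)

        corpus[pid] = rec
        gt.systems[pid] = label

        # registry snapshot: most patients present with true components;
        # occasional conflicts and omissions exercise the comparison logic
        if rng.random() < 0.8:
            for comp, surface in (("acetabular", ace), ("femoral", fem)):
                if surface.startswith("Zimmer Biomet "):
                    man, model = "Zimmer Biomet", surface[len("Zimmer Biomet "):]
                elif surface.startswith("Depuy "):
                    man, model = "Depuy", surface[len("Depuy "):]
                else:
                    man, model = "", surface
                if rng.random() < 0.05:
                    model = "Unknown"
                if rng.random() < 0.1:
                    continue
                gt.registry.append(
                    RegistryRecord(pid, index_date, comp, man, model)
                )

        rows.append(
            {
                "patient_id": pid,
                "implant_system": label,
                "age_at_surgery": age,
                "gender": gender,
                "race": race,
                "ethnicity": ethnicity,
                "cci": cci,
                "follow_up": follow_up,
                "event_revision": int(had_revision),
                "time_to_revision": time_to_revision,
                "had_revision": bool(had_revision),
                "pain_count_prior": pain_prior,
                "pain_count_post": pain_post,
                "index_date": index_date,
                "single_implant": True,
            }
        )

    gt.covariates = pd.DataFrame(rows)
    if len(gt.covariates):
        gt.covariates["cci_category"] = gt.covariates["cci"].map(
            lambda c: ("none", "low", "moderate")[c] if c < 3 else "high"
        )
    return corpus, gt


def simulate_votes(
    gold_labels: Sequence[int],
    accuracies: Sequence[float],
    propensities: Sequence[float],
    seed: int = 0,
):
    """LF vote matrix with known accuracy/propensity truth.

    ``gold_labels`` in {-1, +1}. Each LF abstains with probability
    1 - beta_j; when it votes it agrees with the gold label with
    probability alpha_j.
    """
    from .weak_supervision import LabelMatrix

    rng = np.random.default_rng(seed)
    y = np.asarray(gold_labels, dtype=int)
    n, m = len(y), len(accuracies)
    votes = np.zeros((n, m), dtype=np.int8)
    for j, (a, b) in enumerate(zip(accuracies, propensities)):
        speaks = rng.random(n) < b
        correct = rng.random(n) < a
        votes[:, j] = np.where(speaks, np.where(correct, y, -y), 0)
    return LabelMatrix(votes, tuple(f"sim_lf_{j}" for j in range(m)))


def simulate_survival(config: SimConfig, n: int | None = None) -> pd.DataFrame:
    """Covariate rows with exponential event times and uniform censoring.

    Hazard for a patient on system s is baseline_hazard * exp(log_HR_s);
    follow-up is uniform over ``follow_up_range``.
    """
    rng = np.random.default_rng(config.seed)
    n = n or config.n_patients
    keys = list(config.system_table)
    probs = np.array([config.system_table[k] for k in keys])
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=n, p=probs)
    labels = [_system_label(*keys[i]) for i in idx]
    hr = np.exp([config.log_hazard_ratios.get(l, 0.0) for l in labels])
    rate = config.baseline_hazard * hr
    t_event = rng.exponential(1.0 / rate)
    censor = rng.uniform(*config.follow_up_range, size=n)
    event = t_event < censor
    return pd.DataFrame(
        {
            "patient_id": [f"S{i:05d}" for i in range(n)],
            "implant_system": labels,
            "age_at_surgery": np.clip(rng.normal(63, 10, n), 30, 90),
            "gender": np.where(rng.random(n) < 0.556, "F", "M"),
            "race": np.array(_RACES)[rng.choice(len(_RACES), n, p=_RACE_P)],
            "ethnicity": np.array(_ETHNICITIES)[rng.choice(len(_ETHNICITIES), n, p=_ETH_P)],
            "cci_category": np.array(CCI_LEVELS)[
                rng.choice(4, n, p=(0.5, 0.25, 0.15, 0.1))
            ],
            "time_to_revision": np.minimum(t_event, censor),
            "event_revision": event.astype(int),
            "follow_up": censor,
            "single_implant": True,
        }
    )


CCI_LEVELS = ("none", "low", "moderate", "high")


def simulate_counts(config: SimConfig, n: int | None = None) -> pd.DataFrame:
    """Covariate rows with negative binomial pain counts.

    mu_i = pain_mean * exp(log_IRR_system + 0.05 * (prior - mean prior));
    dispersion is the NB size parameter k (k -> inf gives Poisson).
    """
    rng = np.random.default_rng(config.seed)
    n = n if n is not None else config.n_patients
    keys = list(config.system_table)
    probs = np.array([config.system_table[k] for k in keys])
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=n, p=probs)
    labels = [_system_label(*keys[i]) for i in idx]
    prior = _draw_nb(rng, config.prior_pain_mean, config.nb_dispersion, n)
    eta = np.log(config.pain_mean) + np.array(
        [config.log_irrs.get(l, 0.0) for l in labels]
    ) + 0.05 * (prior - config.prior_pain_mean)
    mu = np.exp(eta)
    k = config.nb_dispersion
    if np.isfinite(k):
        lam = rng.gamma(shape=k, scale=mu / k)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    return pd.DataFrame(
        {
            "patient_id": [f"C{i:05d}" for i in range(n)],
            "implant_system": labels,
            "age_at_surgery": np.clip(rng.normal(63, 10, n), 30, 90),
            "gender": np.where(rng.random(n) < 0.556, "F", "M"),
            "race": np.array(_RACES)[rng.choice(len(_RACES), n, p=_RACE_P)],
            "ethnicity": np.array(_ETHNICITIES)[rng.choice(len(_ETHNICITIES), n, p=_ETH_P)],
            "pain_count_prior": prior,
            "pain_count_post": counts,
            "follow_up": rng.uniform(*config.follow_up_range, size=n),
            "single_implant": True,
        }
    )
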