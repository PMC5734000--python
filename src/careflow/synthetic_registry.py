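"""Synthetic reimbursement-register generator with planted practice archetypes.

The real register behind this kind of analysis (a national claims database) is
not publicly available, so every downstream stage is exercised on synthetic
event tables that emulate its structure: six ischemic-heart-disease procedures
in three care categories, 180-day-gap-delimited care episodes, regional
practice-style archetypes shared by the centers of an area, per-pathway
365-day mortality, and heterogeneous center volumes.

The generator is ground-truth-preserving by construction: every emitted series
is guaranteed to survive phantom-merging, index qualification and gap
splitting unchanged, so the intended pathway labels are recoverable exactly
(in the absence of planted deaths, which legitimately terminate series).
All distributional choices are test scaffolding, not claims about any real
register.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .event_pipeline import REGISTRY_COLUMNS
from .reference import (
    CA,
    CABG,
    DEATH,
    ECG_STRESS,
    ECHO_STRESS,
    PCI,
    PROCEDURES,
    REFERENCE_CLUSTER_SPECTRA_PCT,
    REFERENCE_CLUSTER_REVASC_PCT,
    REFERENCE_MORTALITY_BY_TYPE_PCT,
    SERIES_TYPES,
    SPECT,
)

#: concrete procedures available per category; the first I event of a series is
#: always CA — PCI/CABG are only ever generated as revascularization follow-ups.
CATEGORY_PROCEDURES = {"E": [ECG_STRESS], "NI": [ECHO_STRESS, SPECT], "I": [CA]}


def default_archetype_spectra() -> list[np.ndarray]:
    """The three published cluster pathway profiles, as probability vectors.

    The printed percentage columns carry rounding (they sum to 99.92-99.94),
    so they are renormalized to exact probability vectors here.
    """
    out = []
    for k in (1, 2, 3):
        v = np.asarray(REFERENCE_CLUSTER_SPECTRA_PCT[k], dtype=float)
        out.append(v / v.sum())
    return out


def separated_archetype_spectra() -> list[np.ndarray]:
    """Three well-separated practice-style profiles for recovery experiments.

    Invasive-direct, noninvasive-imaging and stepwise-guideline styles; their
    pairwise Pearson correlations are below 0.5, unlike the published
    aggregate cluster profiles (which are nearly collinear because every
    cluster shares the dominant single-stress-test component).
    """
    t = {s: i for i, s in enumerate(SERIES_TYPES)}

    def vec(**shares):
        v = np.full(len(SERIES_TYPES), 0.004)
        for k, s in shares.items():
            v[t[k.replace("_", "-")]] = s
        return v / v.sum()

    invasive = vec(E=0.28, E_I=0.12, I=0.30, I_E=0.12, NI=0.04, NI_I=0.03, I_NI=0.04)
    imaging = vec(E=0.15, E_NI=0.20, NI=0.35, NI_E=0.12, NI_I=0.08, NI_E_I=0.03,
                  E_NI_I=0.04)
    stepwise = vec(E=0.25, E_NI=0.15, E_NI_I=0.15, E_I=0.10, I_NI=0.15, I_NI_E=0.05,
                   I=0.05, NI_I=0.05)
    return [invasive, imaging, stepwise]


def default_mortality_by_type() -> np.ndarray:
    return np.asarray(REFERENCE_MORTALITY_BY_TYPE_PCT, dtype=float) / 100.0


def default_revasc_prob() -> list[float]:
    return [REFERENCE_CLUSTER_REVASC_PCT[k] / 100.0 for k in (1, 2, 3)]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic register.

    ``spectrum_noise`` is a per-center deviation scale: a center's own pathway
    distribution is drawn from Dirichlet(archetype / spectrum_noise), so 0
    means every center reproduces its archetype exactly and larger values mean
    larger practice deviations (the default 0.002, i.e. concentration 500,
    gives a ~1-percentage-point standard deviation on a 5% pathway share).
    """

    n_zip_areas: int = 90
    n_centers: int = 30
    n_patients: int = 60000
    n_archetypes: int = 3
    archetype_spectra: Sequence[np.ndarray] = field(default_factory=default_archetype_spectra)
    spectrum_noise: float = 0.002
    zip_archetype_map: Mapping[str, int] | None = None
    observation_days: int = 1826
    gap_days: int = 180
    mortality_by_type: np.ndarray = field(default_factory=default_mortality_by_type)
    intra_series_gap_max: int = 60
    revasc_prob: Sequence[float] | float = field(default_factory=default_revasc_prob)
    volume_sigma: float = 0.5
    extra_series_prob: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if len(self.archetype_spectra) != self.n_archetypes:
            raise ValueError(
                f"{len(self.archetype_spectra)} archetype spectra for "
                f"{self.n_archetypes} archetypes"
            )
        for i, spec in enumerate(self.archetype_spectra):
            v = np.asarray(spec, dtype=float)
            if v.shape != (len(SERIES_TYPES),):
                raise ValueError(f"archetype {i} spectrum is not length 15")
            if (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"archetype {i} spectrum is not a probability vector")
        if self.intra_series_gap_max >= self.gap_days:
            raise ValueError("intra_series_gap_max must be < gap_days")
        if self.n_archetypes > self.n_centers:
            raise ValueError("more archetypes than centers")
        if self.n_zip_areas < self.n_centers:
            raise ValueError("need at least one ZIP area per center")
        if self.observation_days < self.gap_days + 366 + 4 * self.intra_series_gap_max:
            raise ValueError("observation horizon too short for a full series plus follow-up")
        if len(np.atleast_1d(self.mortality_by_type)) not in (1, len(SERIES_TYPES)):
            raise ValueError("mortality_by_type must be scalar or length 15")

    # derived layout -------------------------------------------------------

    def center_ids(self) -> list[str]:
        return [f"C{i:03d}" for i in range(self.n_centers)]

    def zip_ids(self) -> list[str]:
        return [f"Z{i:04d}" for i in range(self.n_zip_areas)]

    def center_archetype(self) -> dict[str, int]:
        """Centers are assigned to archetypes in contiguous blocks (a stylized
        stand-in for geographic contiguity of practice regions)."""
        return {
            cid: (i * self.n_archetypes) // self.n_centers
            for i, cid in enumerate(self.center_ids())
        }

    def zip_center(self) -> dict[str, str]:
        centers = self.center_ids()
        return {z: centers[i % self.n_centers] for i, z in enumerate(self.zip_ids())}

    def derived_zip_archetype_map(self) -> dict[str, int]:
        if self.zip_archetype_map is not None:
            return dict(self.zip_archetype_map)
        ca = self.center_archetype()
        return {z: ca[c] for z, c in self.zip_center().items()}

    def revasc_prob_for(self, archetype: int) -> float:
        if np.isscalar(self.revasc_prob):
            return float(self.revasc_prob)
        probs = list(self.revasc_prob)
        return float(probs[archetype % len(probs)])

    def mortality_for(self, type_index: int) -> float:
        m = np.atleast_1d(np.asarray(self.mortality_by_type, dtype=float))
        return float(m[0]) if m.size == 1 else float(m[type_index])


@dataclass
class SyntheticTruth:
    """Planted ground truth: archetype per center and the intended (emitted)
    pathway labels per patient, in series order."""

    center_archetype: dict
    patient_series_types: dict
    zip_center: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "center_archetype": self.center_archetype,
                    "patient_series_types": self.patient_series_types,
                    "zip_center": self.zip_center,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["center_archetype"], d["patient_series_types"], d.get("zip_center", {}))


def _realize_series(rng, label: str, index_day: int, gap_max: int, revasc_p: float):
    """Concrete (day, procedure) list realizing one pathway label.

    Events appear in the label's first-occurrence order with gaps of
    1..gap_max days; if the series contains a CA, a PCI/CABG follow-up is
    appended with probability ``revasc_p`` within gap_max days of the CA.
    """
    day = index_day
    events = []
    ca_day = None
    for k, cat in enumerate(label.split("-")):
        if k > 0:
            day += int(rng.integers(1, gap_max + 1))
        procs = CATEGORY_PROCEDURES[cat]
        proc = procs[int(rng.integers(len(procs)))] if len(procs) > 1 else procs[0]
        if cat == "I":
            ca_day = day
        events.append((day, proc))
    if ca_day is not None and rng.random() < revasc_p:
        rv_day = ca_day + int(rng.integers(1, gap_max + 1))
        rv = PCI if rng.random() < 0.5 else CABG
        events.append((rv_day, rv))
        events.sort(key=lambda t: t[0])
    return events


def generate_registry(config: SimulationConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a synthetic event table plus its planted ground truth.

    Deterministic given ``config.seed``.  Emitted series are separated by more
    than ``gap_days`` event-free days, start at least ``gap_days`` days into
    observation, keep intra-series gaps at most ``intra_series_gap_max`` days,
    and route every event of a patient to the single center serving the
    patient's ZIP area.  Deaths are Bernoulli draws per pathway type, placed
    after the series' last care event and within 365 days of its index event.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    zip_ids = config.zip_ids()
    zip_center = config.zip_center()
    center_archetype = config.center_archetype()
    archetypes = [np.asarray(a, dtype=float) for a in config.archetype_spectra]

    # per-center pathway distribution: archetype, optionally Dirichlet-perturbed
    center_spectrum = {}
    for cid in config.center_ids():
        base = archetypes[center_archetype[cid]]
        if config.spectrum_noise > 0:
            conc = np.maximum(base, 1e-12) / config.spectrum_noise
            center_spectrum[cid] = rng.dirichlet(conc)
        else:
            center_spectrum[cid] = base

    # heterogeneous center volumes via lognormal ZIP weights
    if config.volume_sigma > 0:
        w = rng.lognormal(mean=0.0, sigma=config.volume_sigma, size=config.n_zip_areas)
    else:
        w = np.ones(config.n_zip_areas)
    zip_of_patient = rng.choice(config.n_zip_areas, size=config.n_patients, p=w / w.sum())

    span_max = 4 * config.intra_series_gap_max
    first_index_hi = config.observation_days - 366
    rows: list = []
    patient_series_types: dict[str, list] = {}

    for p in range(config.n_patients):
        pid = f"P{p:06d}"
        zid = zip_ids[zip_of_patient[p]]
        cid = zip_center[zid]
        arch = center_archetype[cid]
        spectrum = center_spectrum[cid]
        revasc_p = config.revasc_prob_for(arch)

        n_series = 1 + (rng.random() < config.extra_series_prob)
        emitted: list[str] = []
        index_day = int(rng.integers(config.gap_days, first_index_hi + 1))
        for _ in range(n_series):
            t_idx = int(rng.choice(len(SERIES_TYPES), p=spectrum))
            label = SERIES_TYPES[t_idx]
            events = _realize_series(
                rng, label, index_day, config.intra_series_gap_max, revasc_p
            )
            emitted.append(label)
            for day, proc in events:
                rows.append((pid, day, zid, cid, proc, 0))
            last_day = events[-1][0]
            died = rng.random() < config.mortality_for(t_idx)
            if died:
                death_day = int(rng.integers(last_day + 1, index_day + 366))
                rows.append((pid, death_day, zid, cid, DEATH, 1))
                break
            # schedule a possible further series after a fresh >gap_days break
            next_lo = last_day + config.gap_days + 1
            next_hi = config.observation_days - 366
            if next_lo > next_hi:
                break
            index_day = int(rng.integers(next_lo, next_hi + 1))
        patient_series_types[pid] = emitted

    registry = pd.DataFrame(rows, columns=REGISTRY_COLUMNS)
    truth = SyntheticTruth(
        center_archetype=center_archetype,
        patient_series_types=patient_series_types,
        zip_center=zip_center,
    )
    return registry, truth


# --- registry I/O ---------------------------------------------------------


def write_registry(registry: pd.DataFrame, path) -> None:
    missing = [c for c in REGISTRY_COLUMNS if c not in registry.columns]
    if missing:
        raise ValueError(f"registry table is missing columns: {missing}")
    registry[REGISTRY_COLUMNS].to_csv(path, index=False)


def read_registry(path) -> pd.DataFrame:
    """Read a registry CSV, reporting malformed rows with their line numbers."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"registry file {path} is missing columns: {missing}")
    out = df[REGISTRY_COLUMNS].copy()
    for col in ("day", "death"):
        numeric = pd.to_numeric(out[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.astype("Int64").astype(float))
        if bad.any():
            # +2: header line plus 1-based numbering
            lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())[:10]]
            raise ValueError(
                f"non-integer {col!r} field in {path} at line(s) {lines}"
            )
        out[col] = numeric.astype(int)
    return out
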