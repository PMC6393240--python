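"""Synthetic-data generators with known ground truth for every pipeline stage.

Two forward models are provided:

* **NMR titrations** — a labelled protein at fixed concentration is titrated
  with its partner on a molar-ratio schedule (default 0:1 to 8:1 in 0.5
  steps, i.e. 17 points at 100 uM).  Each reporter residue carries a
  saturating shift pair (ddH_max, ddN_max); the observed shift at each
  point is reference + bound_fraction x ddmax + Gaussian noise, with the
  bound fraction from the depletion-corrected single-site model.  An
  optional broadening model attenuates peak intensities geometrically with
  the molar ratio, emulating intermediate exchange.

* **ALEX photon streams** — fluorescent bursts arrive as a Poisson process;
  each burst belongs to a species (dual-labelled, donor-only,
  acceptor-only) with ground-truth (E, S), and its DD/DA/AA photon counts
  are multinomial with expectations matching E = DA/(DD+DA) and
  S = (DD+DA)/(DD+DA+AA).  Photon times are placed into the correct ALEX
  half-slots; Poisson background is interleaved per detection channel.

All generators are seed-deterministic, and ground-truth annotations are
retained so downstream stages can be tested against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding_fit import bound_fraction
from .csp_mapping import PeakList, TitrationSeries
from .smfret import (
    ACCEPTOR,
    DONOR,
    AA,
    DA,
    DD,
    DEFAULT_ALTERNATION_PERIOD,
    IGNORED,
    PhotonStream,
)

__all__ = [
    "TitrationScenario",
    "PhotonScenario",
    "Species",
    "PhotonAnnotations",
    "make_titration_scenario",
    "simulate_titration",
    "simulate_photon_stream",
    "scenario_presets",
    "PRESET_E_STAR",
    "PRESET_KD_UM",
    "DNAA_INTERFACE",
    "DNAD_INTERFACE",
    "DEFAULT_RATIO_SCHEDULE",
]

# ---------------------------------------------------------------------------
# measurement-condition constants (one documented place)

#: apparent FRET efficiency regimes of the filament experiments
PRESET_E_STAR = {
    "filament_alone": 0.70,       # DnaA-DNA filament, no remodeller
    "filament_plus_dnad": 0.50,   # + full-length DnaD (or its DNA-binding-dead truncation)
    "filament_plus_ddbh2": 0.60,  # + the isolated DDBH2 domain
}

#: dissociation constants (uM) of the two titration directions
PRESET_KD_UM = {
    "titration_forward": 768.0,  # DDBH2 into labelled DnaA domain I
    "titration_reverse": 665.0,  # DnaA domain I into labelled DDBH2
}

#: the nine-residue interaction patch on DnaA domain I (residue -> 3-letter name)
DNAA_INTERFACE = {
    17: "LYS", 20: "SER", 23: "SER", 49: "PHE", 50: "ALA",
    52: "ASP", 53: "TRP", 55: "GLU", 60: "HIS",
}

#: the nine-residue patch on the DnaD DDBH2 domain
DNAD_INTERFACE = {
    129: "LEU", 130: "TYR", 132: "ILE", 133: "PHE", 134: "GLU",
    135: "GLU", 164: "LYS", 169: "GLU", 171: "VAL",
}

#: molar-ratio schedule: 0:1 to 8:1 in 0.5 steps (17 points)
DEFAULT_RATIO_SCHEDULE = tuple(np.arange(0.0, 8.01, 0.5))

DEFAULT_LABELLED_CONC_UM = 100.0
DEFAULT_SHIFT_NOISE_PPM = 0.002  # both dimensions, 1H ppm scale

_NON_INTERFACE_NAMES = (
    "GLY", "THR", "VAL", "LEU", "ILE", "MET", "ASN", "GLN", "ARG", "TYR",
)


# ---------------------------------------------------------------------------
# NMR titration generator


@dataclass
class TitrationScenario:
    """Ground truth for one synthetic titration.

    ``residues`` columns: residue_number, residue_name, ref_dH, ref_dN,
    ddH_max, ddN_max, attenuation_factor (I/I0 per unit molar ratio; 1.0 =
    no broadening).
    """

    Kd: float  # uM
    residues: pd.DataFrame
    P: float = DEFAULT_LABELLED_CONC_UM  # uM
    ratios: tuple = DEFAULT_RATIO_SCHEDULE
    noise_sd: float = DEFAULT_SHIFT_NOISE_PPM  # ppm
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.Kd <= 0 or self.P <= 0:
            raise ValueError("Kd and P must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.ratios[0] != 0:
            raise ValueError("ratio schedule must start at 0")

    @property
    def interface_residues(self) -> list[int]:
        sel = (self.residues["ddH_max"] != 0) | (self.residues["ddN_max"] != 0)
        return sorted(self.residues.loc[sel, "residue_number"])


def make_titration_scenario(
    Kd: float = PRESET_KD_UM["titration_forward"],
    interface: dict[int, str] | None = None,
    n_residues: int = 60,
    start_residue: int = 2,
    P: float = DEFAULT_LABELLED_CONC_UM,
    ratios: tuple = DEFAULT_RATIO_SCHEDULE,
    noise_sd: float = DEFAULT_SHIFT_NOISE_PPM,
    broadening_factor: float | None = None,
    name: str = "custom",
) -> TitrationScenario:
    """Build a titration scenario with a planted interface.

    Interface residues (default: the nine-residue DnaA-domain-I patch) get
    saturating shifts spread over 0.15-0.28 ppm (1H) and 0.6-1.1 ppm (15N),
    sized so the endpoint CSP statistics land near the magnitudes observed
    in real interface titrations; all other residues get small secondary
    shifts (< 0.01 ppm combined) emulating minor allosteric ripple on top
    of the measurement noise.  Reference peak positions are drawn once from
    a fixed internal seed so a scenario is a deterministic object.
    """
    if interface is None:
        interface = DNAA_INTERFACE
    numbers = list(range(start_residue, start_residue + n_residues))
    missing = [r for r in interface if r not in numbers]
    if missing:
        raise ValueError(f"interface residues outside residue range: {missing}")

    rng = np.random.default_rng(20240917)  # scenario geometry, not noise
    iface = sorted(interface)
    ddh = dict(zip(iface, np.linspace(0.15, 0.28, len(iface))))
    ddn = dict(zip(iface, np.linspace(0.60, 1.10, len(iface))))
    rows = []
    for i, resnum in enumerate(numbers):
        if resnum in interface:
            name3 = interface[resnum]
            ddh_max, ddn_max = ddh[resnum], ddn[resnum]
        else:
            name3 = _NON_INTERFACE_NAMES[i % len(_NON_INTERFACE_NAMES)]
            ddh_max = float(rng.uniform(0.0, 0.012))
            ddn_max = float(rng.uniform(0.0, 0.05))
        rows.append(
            {
                "residue_number": resnum,
                "residue_name": name3,
                "ref_dH": float(rng.uniform(6.5, 10.0)),
                "ref_dN": float(rng.uniform(105.0, 130.0)),
                "ddH_max": ddh_max,
                "ddN_max": ddn_max,
                "attenuation_factor": broadening_factor if broadening_factor else 1.0,
            }
        )
    return TitrationScenario(
        Kd=Kd, residues=pd.DataFrame(rows), P=P, ratios=tuple(ratios),
        noise_sd=noise_sd, name=name,
    )


def simulate_titration(scenario: TitrationScenario, seed: int) -> TitrationSeries:
    """Forward-simulate the HSQC titration of a scenario.

    The reference point (ratio 0) is noise-free by construction of the CSP
    definition: noise is added to every point including the reference, so
    CSPs carry noise from both endpoints, as in a real pair of spectra.
    """
    rng = np.random.default_rng(seed)
    res = scenario.residues
    points = []
    for ratio in scenario.ratios:
        L = ratio * scenario.P
        fb = bound_fraction(scenario.P, L, scenario.Kd)
        dH = res["ref_dH"] + fb * res["ddH_max"] + rng.normal(0, scenario.noise_sd, len(res))
        dN = res["ref_dN"] + fb * res["ddN_max"] + rng.normal(0, scenario.noise_sd, len(res))
        intensity = res["attenuation_factor"] ** ratio
        peaks = PeakList(
            pd.DataFrame(
                {
                    "residue_number": res["residue_number"],
                    "residue_name": res["residue_name"],
                    "dH_ppm": dH,
                    "dN_ppm": dN,
                    "intensity": intensity,
                }
            )
        )
        points.append((float(ratio), peaks))
    return TitrationSeries(
        labelled_protein_concentration=scenario.P, points=points
    )


# ---------------------------------------------------------------------------
# ALEX photon-stream generator


@dataclass
class Species:
    """One burst species with its ground-truth ALEX coordinates."""

    name: str
    fraction: float
    E_true: float  # apparent FRET efficiency of the species
    S_true: float  # labelling stoichiometry
    brightness: float = 100.0  # detected photons per ms while in the spot

    def count_probabilities(self) -> np.ndarray:
        """(p_DD, p_DA, p_AA) such that E[DA/(DD+DA)] -> E_true and
        E[(DD+DA)/total] -> S_true."""
        s, e = self.S_true, self.E_true
        return np.array([s * (1 - e), s * e, 1 - s])


@dataclass
class PhotonScenario:
    """Ground truth for one simulated ALEX measurement."""

    species: list[Species]
    duration: float = 60.0  # s
    burst_rate: float = 40.0  # bursts/s (all species combined)
    mean_burst_duration_ms: float = 1.0  # exponential mean
    background_rate: float = 1000.0  # photons/s per detection channel
    alternation_period: float = DEFAULT_ALTERNATION_PERIOD  # 50 us = 20 kHz
    name: str = "custom"

    def __post_init__(self) -> None:
        fractions = np.array([sp.fraction for sp in self.species], dtype=float)
        if not np.isclose(fractions.sum(), 1.0):
            raise ValueError("species fractions must sum to 1")
        if np.any(fractions < 0) or self.background_rate < 0:
            raise ValueError("fractions and rates must be >= 0")
        if self.duration <= 0 or self.burst_rate <= 0:
            raise ValueError("duration and burst_rate must be > 0")


@dataclass
class PhotonAnnotations:
    """Ground truth aligned with the sorted photon stream."""

    bursts: pd.DataFrame  # start, stop, species, E_true, S_true, DD, DA, AA
    photon_labels: np.ndarray  # intended DD/DA/AA label per photon
    is_background: np.ndarray  # bool per photon
    burst_id: np.ndarray  # index into bursts, -1 for background


def _fold_into_slot(
    t: np.ndarray, period: float, green: bool, rng: np.random.Generator
) -> np.ndarray:
    """Move timestamps into the requested half-slot of their own period."""
    half = period / 2.0
    phase = np.mod(t, period)
    base = t - phase
    within = rng.uniform(0, half, size=t.shape)  # uniform inside the slot
    return base + (0.0 if green else half) + within


def simulate_photon_stream(
    scenario: PhotonScenario, seed: int
) -> tuple[PhotonStream, PhotonAnnotations]:
    """Simulate one ALEX measurement; returns the stream plus annotations."""
    rng = np.random.default_rng(seed)
    period = scenario.alternation_period
    fractions = np.array([sp.fraction for sp in scenario.species])

    n_bursts = rng.poisson(scenario.burst_rate * scenario.duration)
    starts = np.sort(rng.uniform(0, scenario.duration, n_bursts))
    durations = rng.exponential(scenario.mean_burst_duration_ms / 1e3, n_bursts)
    species_idx = rng.choice(len(scenario.species), size=n_bursts, p=fractions)

    times: list[np.ndarray] = []
    chans: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    burst_ids: list[np.ndarray] = []
    burst_rows = []
    for b in range(n_bursts):
        sp = scenario.species[species_idx[b]]
        n = rng.poisson(sp.brightness * durations[b] * 1e3)
        counts = rng.multinomial(n, sp.count_probabilities()) if n else np.zeros(3, int)
        t_raw = rng.uniform(starts[b], starts[b] + durations[b], n)
        lab = np.repeat([DD, DA, AA], counts)
        t = np.empty(n)
        green = lab != AA
        t[green] = _fold_into_slot(t_raw[green], period, True, rng)
        t[~green] = _fold_into_slot(t_raw[~green], period, False, rng)
        ch = np.where(lab == DD, DONOR, ACCEPTOR).astype(np.int8)
        times.append(t)
        chans.append(ch)
        labels.append(lab)
        burst_ids.append(np.full(n, b))
        burst_rows.append(
            {
                "start": starts[b],
                "stop": starts[b] + durations[b],
                "species": sp.name,
                "E_true": sp.E_true,
                "S_true": sp.S_true,
                "n_photons": int(n),
                "DD": int(counts[0]),
                "DA": int(counts[1]),
                "AA": int(counts[2]),
            }
        )

    # Poisson background, per detection channel, uniform over slots
    for ch_code in (DONOR, ACCEPTOR):
        n_bg = rng.poisson(scenario.background_rate * scenario.duration)
        t_bg = rng.uniform(0, scenario.duration, n_bg)
        green = np.mod(t_bg, period) < period / 2
        if ch_code == DONOR:
            lab = np.where(green, DD, IGNORED)  # red-slot donor: no ALEX signal
        else:
            lab = np.where(green, DA, AA)
        times.append(t_bg)
        chans.append(np.full(n_bg, ch_code, dtype=np.int8))
        labels.append(lab.astype(np.int64))
        burst_ids.append(np.full(n_bg, -1))

    t_all = np.concatenate(times)
    order = np.argsort(t_all, kind="stable")
    stream = PhotonStream(
        timestamps=t_all[order],
        channels=np.concatenate(chans)[order],
        alternation_period=period,
    )
    ann = PhotonAnnotations(
        bursts=pd.DataFrame(burst_rows),
        photon_labels=np.concatenate(labels)[order],
        is_background=(np.concatenate(burst_ids)[order] < 0),
        burst_id=np.concatenate(burst_ids)[order],
    )
    return stream, ann


# ---------------------------------------------------------------------------
# presets


def _fret_preset(name: str, e_true: float) -> PhotonScenario:
    return PhotonScenario(
        species=[
            Species("dual", 0.60, e_true, 0.55),
            Species("donor_only", 0.20, 0.0, 1.0),
            Species("acceptor_only", 0.20, 0.0, 0.0),
        ],
        duration=150.0,
        name=name,
    )


def scenario_presets() -> dict[str, TitrationScenario | PhotonScenario]:
    """Named measurement scenarios.

    FRET presets place the dual-labelled species at the three observed E*
    regimes (filament alone 0.7; + DnaD 0.5; + DDBH2 0.6) alongside
    donor-only and acceptor-only species.  Titration presets plant the
    nine-residue patch of each partner at its fitted dissociation constant.
    """
    presets: dict[str, TitrationScenario | PhotonScenario] = {}
    for name, e in PRESET_E_STAR.items():
        presets[name] = _fret_preset(name, e)
    presets["titration_forward"] = make_titration_scenario(
        Kd=PRESET_KD_UM["titration_forward"],
        interface=DNAA_INTERFACE,
        start_residue=2,
        name="titration_forward",
    )
    presets["titration_reverse"] = make_titration_scenario(
        Kd=PRESET_KD_UM["titration_reverse"],
        interface=DNAD_INTERFACE,
        n_residues=60,
        start_residue=125,
        name="titration_reverse",
    )
    return presets
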