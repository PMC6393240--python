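"""Chemical shift perturbation (CSP) mapping from HSQC titration peak lists.

A CSP combines the change in amide 1H and 15N chemical shifts of a residue
between a reference (apo) spectrum and a titration point into one weighted
scalar.  Residues whose CSP exceeds mu + sigma or mu + 2*sigma of the
per-profile CSP distribution are classified as significantly perturbed and
mark the binding interface.  Intensity ratios I/I0 quantify line broadening
for interactions in the intermediate-exchange regime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PeakList",
    "TitrationSeries",
    "CSPProfile",
    "compute_csp",
    "compute_thresholds",
    "compute_csp_profile",
    "intensity_attenuation",
    "read_peak_list",
    "write_peak_list",
    "read_titration_manifest",
]

#: default 15N weighting factor relative to 1H
DEFAULT_NITROGEN_WEIGHT = 0.14

CONVENTIONS = ("scaled_squared", "literal")
SIGMA_ESTIMATORS = ("population", "sample")

CLASS_NOT_SIGNIFICANT = "not_significant"
CLASS_ABOVE_SIGMA = "above_mu_plus_sigma"
CLASS_ABOVE_2SIGMA = "above_mu_plus_2sigma"

PEAK_COLUMNS = ["residue_number", "residue_name", "dH_ppm", "dN_ppm"]


@dataclass
class PeakList:
    """One HSQC peak list: one row per assigned backbone amide."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        missing = [c for c in PEAK_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"peak list missing columns: {missing}")
        if "intensity" not in df.columns:
            df["intensity"] = np.nan
        df["residue_number"] = df["residue_number"].astype(int)
        for col in ("dH_ppm", "dN_ppm"):
            df[col] = df[col].astype(float)
            if not np.isfinite(df[col]).all():
                raise ValueError(f"non-finite values in {col}")
        if df["residue_number"].duplicated().any():
            dupes = df.loc[df["residue_number"].duplicated(), "residue_number"]
            raise ValueError(f"duplicate residue numbers: {sorted(set(dupes))}")
        inten = df["intensity"].astype(float)
        if (inten.dropna() < 0).any():
            raise ValueError("negative intensities")
        df["intensity"] = inten
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "PeakList":
        """Build from (resnum, resname, dH, dN[, intensity]) tuples."""
        rows = []
        for rec in records:
            row = dict(zip(PEAK_COLUMNS + ["intensity"], rec))
            rows.append(row)
        return cls(pd.DataFrame(rows))

    @property
    def residue_numbers(self) -> np.ndarray:
        return self.data["residue_number"].to_numpy()

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("residue_number")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class TitrationSeries:
    """Ordered titration: (molar ratio, peak list) points plus the labelled
    protein concentration in uM.  The first point must be the apo reference
    (ratio 0) and ratios must strictly increase."""

    labelled_protein_concentration: float
    points: list[tuple[float, PeakList]]

    def __post_init__(self) -> None:
        if self.labelled_protein_concentration <= 0:
            raise ValueError("labelled_protein_concentration must be > 0")
        if not self.points:
            raise ValueError("titration series needs at least one point")
        ratios = [float(r) for r, _ in self.points]
        if ratios[0] != 0:
            raise ValueError("first titration point must have molar ratio 0")
        if any(b <= a for a, b in zip(ratios, ratios[1:])):
            raise ValueError("molar ratios must be strictly increasing")

    @property
    def ratios(self) -> np.ndarray:
        return np.array([r for r, _ in self.points], dtype=float)

    @property
    def reference(self) -> PeakList:
        return self.points[0][1]

    def peaks_at(self, ratio: float) -> PeakList:
        for r, peaks in self.points:
            if np.isclose(r, ratio):
                return peaks
        raise KeyError(f"no titration point at molar ratio {ratio}")


@dataclass
class CSPProfile:
    """Per-residue CSPs with the mu/sigma significance machinery.

    ``table`` columns: residue_number, residue_name, csp, csp_class.
    ``excluded`` maps residue number -> reason string.
    """

    table: pd.DataFrame
    mu: float
    sigma: float
    threshold_1: float
    threshold_2: float
    excluded: dict[int, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def residues_in_class(self, csp_class: str) -> list[int]:
        sel = self.table["csp_class"] == csp_class
        return self.table.loc[sel, "residue_number"].tolist()

    @property
    def significant_residues(self) -> list[int]:
        """Residues above mu + sigma (either tier)."""
        return sorted(
            self.residues_in_class(CLASS_ABOVE_SIGMA)
            + self.residues_in_class(CLASS_ABOVE_2SIGMA)
        )

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def summary(self) -> dict:
        return {
            "mu": self.mu,
            "sigma": self.sigma,
            "threshold_1": self.threshold_1,
            "threshold_2": self.threshold_2,
            "n_residues": int(len(self.table)),
            "n_above_mu_plus_sigma": len(self.residues_in_class(CLASS_ABOVE_SIGMA)),
            "n_above_mu_plus_2sigma": len(self.residues_in_class(CLASS_ABOVE_2SIGMA)),
            "excluded": {str(k): v for k, v in sorted(self.excluded.items())},
            **self.metadata,
        }

    def write_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# core CSP arithmetic


def compute_csp(
    dH_delta,
    dN_delta,
    nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT,
    convention: str = "scaled_squared",
):
    """Weighted combined 1H/15N shift perturbation, in ppm.

    scaled_squared : sqrt(0.5 * (dH^2 + (w * dN)^2))   -- standard weighting
    literal        : sqrt(0.5 * (dH^2 + w * dN^2))     -- the printed-formula
                     reading with the weight outside the square

    Both are non-negative and invariant under sign flips of either input;
    they coincide when w == 1 or dN == 0.
    """
    if nitrogen_weight <= 0:
        raise ValueError("nitrogen_weight must be > 0")
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; choose from {CONVENTIONS}")
    dH = np.asarray(dH_delta, dtype=float)
    dN = np.asarray(dN_delta, dtype=float)
    if not (np.all(np.isfinite(dH)) and np.all(np.isfinite(dN))):
        raise ValueError("non-finite shift differences")
    if convention == "scaled_squared":
        out = np.sqrt(0.5 * (dH**2 + (nitrogen_weight * dN) ** 2))
    else:
        out = np.sqrt(0.5 * (dH**2 + nitrogen_weight * dN**2))
    return out if out.ndim else float(out)


def compute_thresholds(
    csp_values: Sequence[float], sigma_estimator: str = "population"
) -> tuple[float, float, float, float]:
    """(mu, sigma, mu + sigma, mu + 2*sigma) of a CSP distribution."""
    if sigma_estimator not in SIGMA_ESTIMATORS:
        raise ValueError(f"unknown sigma estimator {sigma_estimator!r}")
    values = np.asarray(list(csp_values), dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 CSP values for mu/sigma thresholds")
    mu = float(values.mean())
    ddof = 0 if sigma_estimator == "population" else 1
    sigma = float(values.std(ddof=ddof))
    return mu, sigma, mu + sigma, mu + 2 * sigma


def classify_csp(csp: float, threshold_1: float, threshold_2: float) -> str:
    """Strictly-greater-than classification against the two tiers."""
    if csp > threshold_2:
        return CLASS_ABOVE_2SIGMA
    if csp > threshold_1:
        return CLASS_ABOVE_SIGMA
    return CLASS_NOT_SIGNIFICANT


def compute_csp_profile(
    series: TitrationSeries,
    endpoint_ratio: float | None = None,
    exclusions: Mapping[int, str] | Iterable[int] = (),
    nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT,
    convention: str = "scaled_squared",
    sigma_estimator: str = "population",
) -> CSPProfile:
    """CSPs of every residue shared between the reference and the endpoint.

    Residues present in the reference but lost (broadened out / overlapped)
    at the endpoint are recorded in ``excluded`` and do not enter mu/sigma.
    ``exclusions`` supplies user exclusions (prolines are absent from HSQC
    peak lists to begin with, so they never appear).
    """
    if endpoint_ratio is None:
        endpoint_ratio = float(series.ratios[-1])
    try:
        endpoint = series.peaks_at(endpoint_ratio)
    except KeyError as err:
        raise ValueError(str(err)) from err
    reference = series.reference

    if isinstance(exclusions, Mapping):
        user_excl = {int(k): str(v) for k, v in exclusions.items()}
    else:
        user_excl = {int(r): "user_excluded" for r in exclusions}

    ref = reference.indexed()
    end = endpoint.indexed()
    excluded: dict[int, str] = {}
    rows = []
    common = 0
    for resnum, ref_row in ref.iterrows():
        if resnum in user_excl:
            excluded[resnum] = user_excl[resnum]
            continue
        if resnum not in end.index:
            excluded[resnum] = "lost/overlapped"
            continue
        common += 1
        end_row = end.loc[resnum]
        csp = compute_csp(
            end_row["dH_ppm"] - ref_row["dH_ppm"],
            end_row["dN_ppm"] - ref_row["dN_ppm"],
            nitrogen_weight=nitrogen_weight,
            convention=convention,
        )
        rows.append(
            {
                "residue_number": int(resnum),
                "residue_name": ref_row["residue_name"],
                "csp": csp,
            }
        )
    if common == 0:
        raise ValueError("no residues shared between reference and endpoint")

    table = pd.DataFrame(rows)
    mu, sigma, t1, t2 = compute_thresholds(table["csp"], sigma_estimator)
    table["csp_class"] = [classify_csp(v, t1, t2) for v in table["csp"]]
    return CSPProfile(
        table=table,
        mu=mu,
        sigma=sigma,
        threshold_1=t1,
        threshold_2=t2,
        excluded=excluded,
        metadata={
            "endpoint_ratio": float(endpoint_ratio),
            "nitrogen_weight": nitrogen_weight,
            "convention": convention,
            "sigma_estimator": sigma_estimator,
        },
    )


def intensity_attenuation(series: TitrationSeries) -> tuple[pd.DataFrame, list[int]]:
    """Per-residue, per-point intensity ratios I/I0 relative to the apo point.

    Returns (table, flagged) where the table has one row per reference
    residue and one column per non-reference molar ratio; residues not
    detectable at a point get ratio 0.  ``flagged`` lists residues whose
    reference intensity is zero or missing (their ratios are NaN).
    """
    ref = series.reference.indexed()
    if ref["intensity"].isna().all():
        raise ValueError("reference point carries no intensities")
    if len(series.points) < 2:
        raise ValueError("need at least one non-reference titration point")

    flagged: list[int] = []
    out = pd.DataFrame(index=ref.index)
    out.index.name = "residue_number"
    i0 = ref["intensity"]
    bad_ref = i0.isna() | (i0 == 0)
    flagged = sorted(int(r) for r in ref.index[bad_ref])

    for ratio, peaks in series.points[1:]:
        col = np.zeros(len(ref))
        pk = peaks.indexed()
        for j, resnum in enumerate(ref.index):
            if bad_ref.loc[resnum]:
                col[j] = np.nan
            elif resnum in pk.index and np.isfinite(pk.loc[resnum, "intensity"]):
                col[j] = pk.loc[resnum, "intensity"] / i0.loc[resnum]
            else:
                col[j] = 0.0  # peak broadened beyond detection
        out[f"ratio_{ratio:g}"] = col
    return out, flagged


# ---------------------------------------------------------------------------
# file I/O: tab-separated peak lists and a YAML/JSON titration manifest


def read_peak_list(path: str | Path) -> PeakList:
    df = pd.read_csv(path, sep="\t")
    return PeakList(df)


def write_peak_list(peaks: PeakList, path: str | Path) -> None:
    df = peaks.data.copy()
    if df["intensity"].isna().all():
        df = df.drop(columns=["intensity"])
    df.to_csv(path, sep="\t", index=False, float_format="%.5f")


def read_titration_manifest(path: str | Path) -> TitrationSeries:
    """Load a titration from a manifest file.

    The manifest (YAML or JSON) holds ``labelled_protein_concentration_uM``
    and a ``points`` list of ``{ratio, file}`` entries with peak-list paths
    relative to the manifest location.
    """
    path = Path(path)
    text = path.read_text()
    manifest = yaml.safe_load(text)
    conc = float(manifest["labelled_protein_concentration_uM"])
    points = []
    for entry in manifest["points"]:
        peak_path = Path(entry["file"])
        if not peak_path.is_absolute():
            peak_path = path.parent / peak_path
        points.append((float(entry["ratio"]), read_peak_list(peak_path)))
    points.sort(key=lambda rp: rp[0])
    return TitrationSeries(labelled_protein_concentration=conc, points=points)
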