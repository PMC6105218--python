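"""Suspect screening: match extracted features against a packaged list of
12 emerging contaminants (artificial sweeteners, pharmaceuticals, parabens)
and assemble presence/absence detection matrices per treatment stage and
extraction protocol.

MS1 matching uses polarity + accurate mass (ppm window against the ion m/z
recomputed from the suspect's formula) + retention time.  Targeted MS/MS
confirmation against the suspect's precursor -> product transition is
recorded as a separate flag, mirroring the full-scan vs targeted-MS/MS
split of the acquisition it models.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .chem import Formula, ion_mz, ppm_error

__all__ = ["SuspectEntry", "Detection", "DetectionMatrix",
           "load_suspects", "load_reference_matrix",
           "screen", "confirm_msms", "build_detection_matrix"]

STAGES = ("hall_of_separators", "secondary_settlement", "effluent")
PROTOCOLS = ("A", "B", "C")


@dataclass(frozen=True)
class SuspectEntry:
    """One row of the packaged suspect list."""

    name: str
    formula: Formula
    polarity: str              # ESI mode the compound is monitored in
    rt_min: float              # retention time, minutes (methanol gradient)
    precursor_mz: float        # published ion m/z (entry's own convention)
    product_mz: float          # targeted-MS/MS product ion, 2-decimal
    collision_energy_v: float
    mz_convention: str = "proton"   # arithmetic that reproduces precursor_mz

    def __post_init__(self) -> None:
        adduct = "M+H" if self.polarity == "positive" else "M-H"
        theo = ion_mz(self.formula, adduct, convention=self.mz_convention)
        if abs(ppm_error(theo, self.precursor_mz)) > 5.0:
            raise ValueError(
                f"{self.name}: precursor {self.precursor_mz} inconsistent with "
                f"{self.formula} under {self.mz_convention} convention ({theo:.4f})")
        if self.product_mz >= self.precursor_mz:
            raise ValueError(f"{self.name}: product m/z must be below precursor")

    @property
    def adduct(self) -> str:
        return "M+H" if self.polarity == "positive" else "M-H"

    def theoretical_mz(self, convention: str = "proton") -> float:
        """Ion m/z recomputed from the formula under a chosen convention."""
        return ion_mz(self.formula, self.adduct, convention=convention)


@dataclass
class Detection:
    """A suspect matched in one sample."""

    suspect: str
    stage: str
    protocol: str
    feature_mz: float
    feature_rt: float
    ppm: float
    d_rt_min: float
    msms_confirmed: bool | None = None   # None = transition not acquired


class DetectionMatrix:
    """Compound x (stage, protocol) presence matrix.

    Serializes to a diff-friendly CSV with ``+`` / ``-`` cells and
    ``stage:protocol`` column headers.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df.astype(bool)

    # -- construction ---------------------------------------------------------
    @classmethod
    def empty(cls, compounds: Sequence[str],
              samples: Sequence[tuple[str, str]]) -> "DetectionMatrix":
        cols = [f"{s}:{p}" for s, p in samples]
        return cls(pd.DataFrame(False, index=list(compounds), columns=cols))

    # -- accessors ------------------------------------------------------------
    @property
    def compounds(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[tuple[str, str]]:
        return [tuple(c.split(":", 1)) for c in self.df.columns]

    def is_detected(self, compound: str, stage: str, protocol: str) -> bool:
        return bool(self.df.at[compound, f"{stage}:{protocol}"])

    def set_detected(self, compound: str, stage: str, protocol: str,
                     value: bool = True) -> None:
        self.df.at[compound, f"{stage}:{protocol}"] = value

    def stage_columns(self, stage: str) -> pd.DataFrame:
        cols = [c for c in self.df.columns if c.split(":", 1)[0] == stage]
        return self.df[cols]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DetectionMatrix) and self.df.equals(other.df)

    # -- serialization --------------------------------------------------------
    def to_symbols(self) -> pd.DataFrame:
        return self.df.map(lambda v: "+" if v else "-")

    def to_csv(self, path: str | Path) -> None:
        out = self.to_symbols()
        out.index.name = "compound"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DetectionMatrix":
        df = pd.read_csv(path, index_col="compound")
        bad = set(df.values.ravel()) - {"+", "-"}
        if bad:
            raise ValueError(f"unexpected cell tokens {bad}")
        return cls(df == "+")


def load_suspects() -> list[SuspectEntry]:
    """The packaged 12-compound suspect list."""
    with resources.files("wwprofiler.data").joinpath("suspects.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [SuspectEntry(name=r["name"], formula=Formula.parse(r["formula"]),
                         polarity=r["polarity"], rt_min=float(r["rt_min"]),
                         precursor_mz=float(r["precursor_mz"]),
                         product_mz=float(r["product_mz"]),
                         collision_energy_v=float(r["collision_energy_v"]),
                         mz_convention=r["mz_convention"])
            for _, r in df.iterrows()]


def load_reference_matrix() -> DetectionMatrix:
    """The packaged reference presence matrix of the 12 suspects across the
    three treatment stages x three extraction protocols."""
    path = resources.files("wwprofiler.data").joinpath("presence_matrix.csv")
    with resources.as_file(path) as p:
        return DetectionMatrix.from_csv(p)


def screen(features: Iterable, suspects: Sequence[SuspectEntry],
           stage: str, protocol: str, *, mz_tol_ppm: float = 2.0,
           rt_tol_min: float = 0.5, convention: str = "proton") -> list[Detection]:
    """Match features of one sample against the suspect list.

    A suspect is detected iff some feature shares its ESI polarity, lies
    within ``mz_tol_ppm`` of the ion m/z computed from the suspect formula,
    and elutes within ``rt_tol_min`` of the suspect's retention time.  The
    best match (smallest |ppm|, then |dRT|) is reported per suspect.
    """
    if mz_tol_ppm <= 0 or rt_tol_min <= 0:
        raise ValueError("tolerances must be positive")
    feats = list(features)
    detections: list[Detection] = []
    for entry in suspects:
        theo = entry.theoretical_mz(convention)
        best: tuple[float, float, object] | None = None
        for f in feats:
            if f.polarity != entry.polarity:
                continue
            ppm = ppm_error(theo, f.mz)
            d_rt = f.rt - entry.rt_min
            if abs(ppm) <= mz_tol_ppm and abs(d_rt) <= rt_tol_min:
                key = (abs(ppm), abs(d_rt))
                if best is None or key < (abs(best[0]), abs(best[1])):
                    best = (ppm, d_rt, f)
        if best is not None:
            ppm, d_rt, f = best
            detections.append(Detection(suspect=entry.name, stage=stage,
                                        protocol=protocol, feature_mz=f.mz,
                                        feature_rt=f.rt, ppm=ppm, d_rt_min=d_rt))
    return detections


def confirm_msms(spectrum: Sequence[tuple[float, float]], entry: SuspectEntry,
                 tol_da: float = 0.01, min_rel_intensity: float = 0.05) -> bool:
    """Confirm a detection from a targeted product-ion spectrum.

    True iff a product peak lies within ``tol_da`` of the entry's transition
    product m/z with at least ``min_rel_intensity`` of the base peak.  The
    published transition masses are 2-decimal values, hence a dalton (not
    ppm) tolerance.
    """
    if not spectrum:
        return False
    base = max(i for _, i in spectrum)
    if base <= 0:
        return False
    for mz, inten in spectrum:
        if abs(mz - entry.product_mz) <= tol_da and inten / base >= min_rel_intensity:
            return True
    return False


def build_detection_matrix(detections: Iterable[Detection],
                           compounds: Sequence[str],
                           samples: Sequence[tuple[str, str]]) -> DetectionMatrix:
    """Aggregate detections into a presence matrix; a cell is ``+`` iff at
    least one Detection exists for that (compound, stage, protocol)."""
    matrix = DetectionMatrix.empty(compounds, samples)
    valid = {(s, p) for s, p in samples}
    for det in detections:
        if (det.stage, det.protocol) in valid and det.suspect in matrix.df.index:
            matrix.set_detected(det.suspect, det.stage, det.protocol)
    return matrix
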