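"""Deterministic molecular-feature extraction from centroided full-scan data.

Vendor "molecular feature extraction" implementations are proprietary; this
module defines a transparent variant with the same contract — noise
filtering, scan-to-scan trace linking, deisotoping, neutral-mass inference —
and makes no attempt to match vendor output peak-for-peak.

Pipeline: centroid peaks below the absolute noise threshold are discarded
first; survivors are grouped into chromatographic traces (same m/z within a
ppm tolerance, strictly consecutive scans, minimum trace length); traces are
then clustered into isotope envelopes by the ~1.00336/z Da spacing and
collapsed to one feature per chemical species, keeping the monoisotopic m/z.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem import IsotopePattern, IsotopePeak, PROTON_MASS
from .io import Scan, read_peaklist

__all__ = ["ExtractionParams", "Trace", "Feature", "extract_features",
           "deisotope", "neutral_mass"]

#: mass difference 13C - 12C, the canonical isotope-envelope spacing
ISOTOPE_SPACING = 1.0033548


@dataclass
class ExtractionParams:
    noise_threshold: float = 1300.0    # absolute counts floor per centroid
    mz_tol_ppm: float = 10.0           # scan-to-scan trace-linking tolerance
    min_scans: int = 3                 # minimum consecutive scans per trace
    isotope_tol_da: float = 0.01       # envelope spacing tolerance
    max_isotope_peaks: int = 4         # M .. M+3
    isotope_rt_tol_min: float = 0.1    # apex co-elution window for envelopes

    def __post_init__(self) -> None:
        vals = (self.noise_threshold, self.mz_tol_ppm, self.min_scans,
                self.isotope_tol_da, self.max_isotope_peaks,
                self.isotope_rt_tol_min)
        if any(v <= 0 for v in vals):
            raise ValueError("all extraction parameters must be positive")


@dataclass
class Trace:
    """A chromatographic trace: one m/z followed across consecutive scans."""

    mz: float                      # intensity-weighted mean m/z
    apex_rt: float
    apex_intensity: float
    apex_scan: int
    total_intensity: float
    scan_ids: list[int]
    intensities: dict[int, float]  # scan index -> intensity

    @property
    def n_scans(self) -> int:
        return len(self.scan_ids)


@dataclass
class Feature:
    """A deisotoped chemical species."""

    mz: float                      # monoisotopic member m/z
    rt: float                      # apex retention time, minutes
    abundance: float               # summed intensity of the monoisotopic trace
    polarity: str
    charge: int = 1
    isotope_pattern: IsotopePattern | None = None   # observed, base = 100
    neutral_mass: float | None = None
    n_scans: int = 1
    feature_id: int = field(default=-1)


def neutral_mass(mz: float, polarity: str) -> float:
    """Neutral monoisotopic mass from a singly charged ion m/z.

    Positive mode assumes [M+H]+ (subtract a proton); negative mode assumes
    [M-H]- (add a proton back).
    """
    if polarity == "positive":
        return mz - PROTON_MASS
    if polarity == "negative":
        return mz + PROTON_MASS
    raise ValueError(f"unknown polarity {polarity!r}")


def _build_traces(scans: list[Scan], params: ExtractionParams) -> list[Trace]:
    if not scans:
        return []
    order = sorted(range(len(scans)), key=lambda i: scans[i].rt_min)
    rts = np.array([scans[i].rt_min for i in order])
    all_mz, all_int, all_scan = [], [], []
    for idx, i in enumerate(order):
        s = scans[i]
        keep = s.intensity >= params.noise_threshold
        if keep.any():
            all_mz.append(s.mz[keep])
            all_int.append(s.intensity[keep])
            all_scan.append(np.full(int(keep.sum()), idx))
    if not all_mz:
        return []
    mz = np.concatenate(all_mz)
    inten = np.concatenate(all_int)
    scan = np.concatenate(all_scan)
    by_mz = np.argsort(mz, kind="stable")
    mz, inten, scan = mz[by_mz], inten[by_mz], scan[by_mz]
    # split sorted m/z into groups at gaps larger than the ppm tolerance
    gaps = np.diff(mz) > params.mz_tol_ppm * 1e-6 * mz[:-1]
    group_starts = np.concatenate([[0], np.flatnonzero(gaps) + 1, [mz.size]])
    traces: list[Trace] = []
    for a, b in zip(group_starts[:-1], group_starts[1:]):
        g_mz, g_int, g_scan = mz[a:b], inten[a:b], scan[a:b]
        by_scan = np.argsort(g_scan, kind="stable")
        g_mz, g_int, g_scan = g_mz[by_scan], g_int[by_scan], g_scan[by_scan]
        # merge duplicates within one scan (intensity-weighted m/z)
        uniq, inv = np.unique(g_scan, return_inverse=True)
        m_int = np.bincount(inv, weights=g_int)
        m_mz = np.bincount(inv, weights=g_int * g_mz) / m_int
        # split at scan gaps: traces must be RT-contiguous
        breaks = np.concatenate([[0], np.flatnonzero(np.diff(uniq) > 1) + 1,
                                 [uniq.size]])
        for u, v in zip(breaks[:-1], breaks[1:]):
            if v - u < params.min_scans:
                continue
            t_scan = uniq[u:v]
            t_int = m_int[u:v]
            t_mz = m_mz[u:v]
            apex = int(np.argmax(t_int))
            traces.append(Trace(
                mz=float(np.average(t_mz, weights=t_int)),
                apex_rt=float(rts[t_scan[apex]]),
                apex_intensity=float(t_int[apex]),
                apex_scan=int(t_scan[apex]),
                total_intensity=float(t_int.sum()),
                scan_ids=[int(x) for x in t_scan],
                intensities={int(k): float(w) for k, w in zip(t_scan, t_int)}))
    traces.sort(key=lambda t: t.mz)
    return traces


def deisotope(traces: list[Trace], params: ExtractionParams,
              polarity: str) -> list[Feature]:
    """Cluster co-eluting traces into isotope envelopes.

    Walking up in m/z, each unassigned trace becomes a monoisotopic
    candidate; members are sought at ``k * 1.00336 / z`` offsets (charge 2
    probed before charge 1, since a z=2 envelope also shows a peak at
    integer spacing), must co-elute within the apex RT window, and must stay
    below 1.1x the monoisotopic abundance (chlorinated species can have
    M+2 ~ M, but never far above it).  The spacing tolerance is applied per
    substitution step (``k * isotope_tol_da`` for the M+k peak): heavy-atom
    isotopes such as 34S or 37Cl shift the aggregated M+2 bin by ~0.01 Da
    relative to pure 13C spacing, and that deviation grows with k.
    Isolated traces become singleton charge-1 features.
    """
    traces = sorted(traces, key=lambda t: t.mz)
    mzs = np.array([t.mz for t in traces])
    assigned = [False] * len(traces)
    features: list[Feature] = []
    for i, mono in enumerate(traces):
        if assigned[i]:
            continue
        assigned[i] = True
        members: list[Trace] = []
        charge = 1
        for z in (2, 1):
            cand_members = []
            for k in range(1, params.max_isotope_peaks):
                target = mono.mz + k * ISOTOPE_SPACING / z
                tol = k * params.isotope_tol_da
                lo = np.searchsorted(mzs, target - tol)
                hi = np.searchsorted(mzs, target + tol)
                best = None
                for j in range(lo, hi):
                    if assigned[j]:
                        continue
                    t = traces[j]
                    if abs(t.apex_rt - mono.apex_rt) > params.isotope_rt_tol_min:
                        continue
                    if t.total_intensity > 1.1 * mono.total_intensity:
                        continue
                    d = abs(t.mz - target)
                    if best is None or d < best[0]:
                        best = (d, j)
                if best is not None:
                    cand_members.append(best[1])
            if cand_members:
                # z=2 requires the half-spacing (k=1) member to be present
                first_target = mono.mz + ISOTOPE_SPACING / z
                has_first = any(abs(traces[j].mz - first_target)
                                <= params.isotope_tol_da for j in cand_members)
                if z == 2 and not has_first:
                    continue
                charge = z
                for j in cand_members:
                    assigned[j] = True
                    members.append(traces[j])
                break
        peaks = [IsotopePeak(0.0, 100.0)]
        for t in sorted(members, key=lambda t: t.mz):
            ab = t.intensities.get(mono.apex_scan)
            if ab is None:
                ab = t.apex_intensity
            peaks.append(IsotopePeak(t.mz - mono.mz,
                                     100.0 * ab / mono.apex_intensity))
        features.append(Feature(
            mz=mono.mz, rt=mono.apex_rt, abundance=mono.total_intensity,
            polarity=polarity, charge=charge,
            isotope_pattern=IsotopePattern(tuple(peaks)),
            neutral_mass=neutral_mass(mono.mz, polarity) if charge == 1 else None,
            n_scans=mono.n_scans))
    features.sort(key=lambda f: f.mz)
    for k, f in enumerate(features):
        f.feature_id = k
    return features


def extract_features(source, params: ExtractionParams | None = None,
                     polarity: str | None = None) -> list[Feature]:
    """Extract deisotoped features from a run.

    ``source`` may be a SyntheticRun, a list of :class:`Scan`, or a path to
    a peak-list CSV / centroided mzML.  Scans of a single ESI polarity are
    processed; pass ``polarity`` to select one from mixed input.  An empty
    run yields an empty list.
    """
    params = params or ExtractionParams()
    scans: list[Scan]
    if isinstance(source, (str, Path)):
        scans = read_peaklist(source)
    elif hasattr(source, "scans"):           # SyntheticRun
        scans = list(source.scans)
        polarity = polarity or source.polarity
    else:
        scans = list(source)
    if polarity is not None:
        scans = [s for s in scans if s.polarity == polarity]
    else:
        pols = {s.polarity for s in scans}
        if len(pols) > 1:
            raise ValueError("mixed polarities: pass polarity= to select one")
        polarity = pols.pop() if pols else "positive"
    traces = _build_traces(scans, params)
    return deisotope(traces, params, polarity)
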