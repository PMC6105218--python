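"""End-to-end campaign orchestration: simulate -> extract -> screen ->
profile, with CSV artifacts for every intermediate.

This is the library core behind the ``run-all`` CLI command; each step can
equally be driven on its own through the stage modules.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chem import IsotopePattern, IsotopePeak
from .extract import ExtractionParams, Feature, extract_features
from .identify import IdentificationCriteria, identify
from .io import PipelineConfig
from .profiling import (RemovalSummary, matrix_effect_table, mass_rt_profile,
                        removal_rates, select_markers)
from .screen import (Detection, DetectionMatrix, build_detection_matrix,
                     confirm_msms, load_suspects, screen)
from .simulate import (GroundTruth, SimulationConfig, SyntheticRun,
                       build_ground_truth, generate_matrix_effect_set,
                       generate_run, write_ground_truth, write_run)

logger = logging.getLogger("wwprofiler")

__all__ = ["CampaignResult", "run_campaign", "features_to_frame",
           "frame_to_features", "candidates_to_frame", "msms_spectrum_for"]


def features_to_frame(features: list[Feature]) -> pd.DataFrame:
    """Feature table with the observed isotope envelope flattened into
    semicolon-joined offset/abundance columns."""
    rows = []
    for f in features:
        pat = f.isotope_pattern
        rows.append({
            "feature_id": f.feature_id, "mz": f.mz, "rt_min": f.rt,
            "abundance": f.abundance, "polarity": f.polarity,
            "charge": f.charge, "neutral_mass": f.neutral_mass,
            "n_scans": f.n_scans,
            "iso_offsets": ";".join(f"{p.shift_da:.6f}" for p in pat) if pat else "",
            "iso_abundances": ";".join(f"{p.abundance_pct:.4f}" for p in pat) if pat else "",
        })
    cols = ["feature_id", "mz", "rt_min", "abundance", "polarity", "charge",
            "neutral_mass", "n_scans", "iso_offsets", "iso_abundances"]
    return pd.DataFrame(rows, columns=cols)


def frame_to_features(df: pd.DataFrame) -> list[Feature]:
    feats = []
    for _, r in df.iterrows():
        pattern = None
        if isinstance(r.get("iso_offsets"), str) and r["iso_offsets"]:
            offs = [float(x) for x in r["iso_offsets"].split(";")]
            abds = [float(x) for x in r["iso_abundances"].split(";")]
            pattern = IsotopePattern(tuple(
                IsotopePeak(o, a) for o, a in zip(offs, abds)))
        feats.append(Feature(
            mz=float(r["mz"]), rt=float(r["rt_min"]),
            abundance=float(r["abundance"]), polarity=str(r["polarity"]),
            charge=int(r["charge"]),
            isotope_pattern=pattern,
            neutral_mass=None if pd.isna(r["neutral_mass"]) else float(r["neutral_mass"]),
            n_scans=int(r["n_scans"]), feature_id=int(r["feature_id"])))
    return feats


def candidates_to_frame(rows: list[tuple[int, object]]) -> pd.DataFrame:
    """Candidate table from (feature_id, CandidateFormula) pairs."""
    recs = []
    for fid, c in rows:
        recs.append({
            "feature_id": fid, "formula": str(c.formula),
            "neutral_mass": c.neutral_mass, "ppm": c.ppm, "rdbe": c.rdbe,
            "iso_dev_pct": c.iso_dev_pct, "score_pct": c.score_pct,
            "accepted": c.accepted, "failed_rule": c.failed_rule or ""})
    cols = ["feature_id", "formula", "neutral_mass", "ppm", "rdbe",
            "iso_dev_pct", "score_pct", "accepted", "failed_rule"]
    return pd.DataFrame(recs, columns=cols)


def msms_spectrum_for(entry) -> list[tuple[float, float]]:
    """Synthetic targeted product-ion spectrum for a suspect: the published
    transition product as base peak plus a residual precursor ion."""
    return [(entry.product_mz, 1000.0), (entry.precursor_mz, 200.0)]


@dataclass
class CampaignResult:
    config: SimulationConfig
    ground_truth: GroundTruth
    detection_matrix: DetectionMatrix
    detections: list[Detection]
    markers: list[str]
    removal: list[RemovalSummary]             # one per (polarity, protocol)
    matrix_effects: pd.DataFrame
    features: dict[tuple[str, str, str], list[Feature]] = field(default_factory=dict)

    def feature_counts(self, polarity: str, protocol: str) -> dict[str, int]:
        return {stage: len(self.features[(stage, protocol, polarity)])
                for stage in self.config.stages}


def run_campaign(config: SimulationConfig,
                 extraction: ExtractionParams | None = None,
                 mz_tol_ppm: float = 2.0, rt_tol_min: float = 0.5,
                 do_identify: bool = False,
                 criteria: IdentificationCriteria | None = None,
                 out_dir: str | Path | None = None,
                 write_peaklists: bool = False) -> CampaignResult:
    """Run the whole chain on synthetic samples for every configured
    (stage, protocol, polarity) and aggregate the campaign outputs."""
    extraction = extraction or ExtractionParams()
    logger.info("campaign seed=%d n_background=%d jitter=%.3g ppm; "
                "extraction noise_threshold=%g mz_tol=%g ppm min_scans=%d; "
                "screening mz_tol=%g ppm rt_tol=%g min",
                config.seed, config.n_background, config.mass_jitter_ppm,
                extraction.noise_threshold, extraction.mz_tol_ppm,
                extraction.min_scans, mz_tol_ppm, rt_tol_min)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "features").mkdir(parents=True, exist_ok=True)
        if write_peaklists:
            (out / "peaklists").mkdir(parents=True, exist_ok=True)
    gt = build_ground_truth(config)
    suspects = gt.suspects
    by_name = {e.name: e for e in suspects}
    all_detections: list[Detection] = []
    features: dict[tuple[str, str, str], list[Feature]] = {}
    candidate_rows: list[tuple[str, int, object]] = []
    for stage in config.stages:
        for protocol in config.protocols:
            for polarity in config.polarities:
                run = generate_run(config, stage, protocol, polarity, gt)
                feats = extract_features(run, extraction)
                features[(stage, protocol, polarity)] = feats
                logger.info("%s/%s/%s: %d features", stage, protocol,
                            polarity, len(feats))
                dets = screen(feats, suspects, stage, protocol,
                              mz_tol_ppm=mz_tol_ppm, rt_tol_min=rt_tol_min,
                              convention=config.mz_convention)
                for det in dets:
                    det.msms_confirmed = confirm_msms(
                        msms_spectrum_for(by_name[det.suspect]),
                        by_name[det.suspect])
                all_detections.extend(dets)
                if do_identify:
                    for f in feats:
                        for cand in identify(f, criteria):
                            candidate_rows.append(
                                (f"{stage}:{protocol}:{polarity}",
                                 f.feature_id, cand))
                if out is not None:
                    name = f"{stage}_{protocol}_{polarity}"
                    features_to_frame(feats).to_csv(
                        out / "features" / f"{name}.csv", index=False)
                    if write_peaklists:
                        write_run(run, out / "peaklists" / f"{name}.csv")
    samples = [(s, p) for s in config.stages for p in config.protocols]
    matrix = build_detection_matrix(all_detections,
                                    [e.name for e in suspects], samples)
    markers = select_markers(matrix)
    removal = []
    for polarity in config.polarities:
        for protocol in config.protocols:
            counts = [len(features[(s, protocol, polarity)])
                      for s in config.stages]
            summary = removal_rates(counts, config.stages, polarity)
            summary = RemovalSummary(
                polarity=f"{polarity}:{protocol}", stages=summary.stages,
                counts=summary.counts,
                removal_vs_previous=summary.removal_vs_previous,
                removal_vs_first=summary.removal_vs_first)
            removal.append(summary)
    me_table = matrix_effect_table(generate_matrix_effect_set(config))
    result = CampaignResult(config=config, ground_truth=gt,
                            detection_matrix=matrix,
                            detections=all_detections, markers=markers,
                            removal=removal, matrix_effects=me_table,
                            features=features)
    if out is not None:
        _write_outputs(result, out, candidate_rows,
                       extraction, mz_tol_ppm, rt_tol_min)
    return result


def _write_outputs(result: CampaignResult, out: Path,
                   candidate_rows, extraction: ExtractionParams,
                   mz_tol_ppm: float, rt_tol_min: float) -> None:
    cfg = result.config
    result.detection_matrix.to_csv(out / "detection_matrix.csv")
    pd.DataFrame({"marker": result.markers}).to_csv(out / "markers.csv",
                                                    index=False)
    pd.concat([s.to_frame() for s in result.removal]).to_csv(
        out / "removal_summary.csv", index=False)
    result.matrix_effects.to_csv(out / "matrix_effects.csv", index=False,
                                 float_format="%.4f")
    write_ground_truth(result.ground_truth, out / "ground_truth.csv")
    dets = pd.DataFrame([d.__dict__ for d in result.detections])
    dets.to_csv(out / "detections.csv", index=False)
    # mass/RT profile of the raw-influent samples, per polarity
    for polarity in cfg.polarities:
        feats = [f for p in cfg.protocols
                 for f in result.features[(cfg.stages[0], p, polarity)]
                 if f.neutral_mass is not None]
        grid, classes = mass_rt_profile([f.neutral_mass for f in feats],
                                        [f.rt for f in feats])
        grid.to_csv(out / f"mass_rt_profile_{polarity}.csv")
        pd.Series(classes.as_dict()).to_csv(
            out / f"mass_classes_{polarity}.csv", header=False)
    if candidate_rows:
        df = candidates_to_frame([(fid, c) for _, fid, c in candidate_rows])
        df.insert(0, "sample", [s for s, _, _ in candidate_rows])
        df.to_csv(out / "candidates.csv", index=False)
    echo = PipelineConfig(
        seed=cfg.seed, out_dir=str(out),
        extraction=extraction.__dict__,
        identification={}, screening={"mz_tol_ppm": mz_tol_ppm,
                                      "rt_tol_min": rt_tol_min},
        simulation={k: v for k, v in cfg.__dict__.items()
                    if not isinstance(v, dict)} | {
                        "survival": {k: list(v) for k, v in cfg.survival.items()},
                        "suppression": cfg.suppression})
    echo.to_json(out / "config.json")
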