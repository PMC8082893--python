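"""End-to-end synthetic placement study.

Reproduces the structure of the cadaveric validation experiment entirely
in silico: a cohort of arm specimens, each contributing a radius and an
ulna; per bone a CT-like and an sCT-like volume segmented to surface
models; one proximal and one distal saw guide designed per bone and
modality (32 guides per modality); six observers placing every guide with
Gaussian placement noise; an emulated optical scan per placement; ICP
registration of each scanned bone back onto the ground-truth model; and
the eight placement errors per placement, followed by the full agreement
analysis (summary table, repeated-measures ANOVA, Bland-Altman with
intra-/inter-observer limits of agreement, outlier flags).

Everything is a deterministic function of ``StudyConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as gstats
from .mesh import signed_vertex_distances, summarize, write_stl
from .placement import placement_error_pipeline
from .registration import ICPParams
from .segmentation import DEFAULT_BONE_LOWER_HU, extract_surface, threshold_segment
from .synth import (
    GuideDesign,
    ObserverErrorModel,
    PhantomSpec,
    ScanNoiseModel,
    design_saw_guide,
    generate_bone_phantom,
    simulate_optical_scan,
    simulate_placement,
)
from .volume import write_volume

__all__ = ["StudyConfig", "StudyResult", "run_full_study", "design_counts"]

BONES = ("radius", "ulna")
LOCATIONS = ("proximal", "distal")
MODALITIES = ("CT", "sCT")
_MODALITY_KIND = {"CT": "ct_like", "sCT": "sct_like"}

# distal ulna is near-circular and anchorless; the radius shaft is more
# eccentric — reflected in the per-bone cross-section defaults
_BONE_GEOMETRY = {
    "radius": dict(cross_section_eccentricity=0.25, shaft_outer_radius=8.5,
                   end_flare_factor=1.6),
    "ulna": dict(cross_section_eccentricity=0.08, shaft_outer_radius=7.0,
                 end_flare_factor=1.35),
}


@dataclass
class StudyConfig:
    """All knobs of one synthetic study run."""

    seed: int = 0
    n_specimens: int = 8
    n_observers: int = 6
    repeat_observer: int = 3  # this observer runs a second session
    observer_error: ObserverErrorModel = field(default_factory=ObserverErrorModel)
    scan_noise: ScanNoiseModel = field(
        default_factory=lambda: ScanNoiseModel(resample_density=0.0)
    )
    icp: ICPParams = field(
        default_factory=lambda: ICPParams(
            max_iterations=200, convergence_tol=1e-4, subsample_size=400
        )
    )
    threshold_lower: float = DEFAULT_BONE_LOWER_HU
    smoothing_factor: float = 0.3
    smoothing_iterations: int = 2
    sct_end_inhomogeneity: bool = True
    tendon_blob_specimen: int | None = 1  # one sCT case shows the artifact
    inter_rule: str = "sd"  # or "max"
    distance_map_vertices: int = 1500
    save_volumes: bool = False
    save_meshes: bool = False

    def __post_init__(self):
        if self.n_observers < 2:
            raise ValueError("need at least 2 observers")
        if self.n_specimens < 1:
            raise ValueError("need at least 1 specimen")
        if isinstance(self.observer_error, dict):
            self.observer_error = ObserverErrorModel(**self.observer_error)
        if isinstance(self.scan_noise, dict):
            self.scan_noise = ScanNoiseModel(**self.scan_noise)
        if isinstance(self.icp, dict):
            self.icp = ICPParams(**self.icp)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def design_counts(config: StudyConfig) -> dict:
    """Enumerate the study design: guides, placements, error values."""
    guides = [
        (s, b, loc, mod)
        for s in range(1, config.n_specimens + 1)
        for b in BONES
        for loc in LOCATIONS
        for mod in MODALITIES
    ]
    per_modality = {mod: sum(1 for g in guides if g[3] == mod) for mod in MODALITIES}
    placements = len(guides) * config.n_observers
    return {
        "guides_total": len(guides),
        "guides_per_modality": per_modality,
        "placements": placements,
        # the headline count: one dT and one dR per placement
        "total_error_values": placements * 2,
    }


@dataclass
class StudyResult:
    records: pd.DataFrame
    summary: pd.DataFrame
    surface_comparison: pd.DataFrame
    anova: dict
    bland_altman: dict
    outliers: pd.DataFrame
    manifest: dict


def _phantom_spec(config: StudyConfig, specimen: int, bone: str, modality: str,
                  seed: int) -> PhantomSpec:
    geom = _BONE_GEOMETRY[bone]
    blob = (
        modality == "sCT"
        and config.tendon_blob_specimen is not None
        and specimen == config.tendon_blob_specimen
        and bone == "radius"
    )
    return PhantomSpec(
        modality=_MODALITY_KIND[modality],
        tendon_blob=blob,
        end_inhomogeneity=config.sct_end_inhomogeneity and modality == "sCT",
        seed=seed,
        **geom,
    )


def run_full_study(config: StudyConfig, output_dir=None) -> StudyResult:
    """Run the whole synthetic study and (optionally) write the report bundle."""
    t_start = time.time()
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    root_ss = np.random.SeedSequence(config.seed)
    # independent, reproducible random streams per pipeline stage
    ss_phantom, ss_place, ss_scan, ss_shuffle = root_ss.spawn(4)

    specimens = range(1, config.n_specimens + 1)
    surface_rows = []
    guide_lookup: dict[tuple, GuideDesign] = {}
    ground_truth = {}
    phantom_streams = {
        (s, b, m): seq
        for (s, b, m), seq in zip(
            [(s, b, m) for s in specimens for b in BONES for m in MODALITIES],
            ss_phantom.spawn(config.n_specimens * len(BONES) * len(MODALITIES)),
        )
    }

    for s in specimens:
        for bone in BONES:
            for modality in MODALITIES:
                seed = int(phantom_streams[(s, bone, modality)].generate_state(1)[0] % (2**31))
                # the phantom geometry is a pure function of the spec's shape
                # parameters, so CT and sCT volumes of one bone share their
                # anatomy; the seed only drives intensity noise
                spec = _phantom_spec(config, s, bone, modality, seed)
                phantom = generate_bone_phantom(spec)
                if modality == "CT":
                    ground_truth[(s, bone)] = phantom.ground_truth_mesh
                mask = threshold_segment(phantom.volume, lower=config.threshold_lower)
                model = extract_surface(
                    mask, config.smoothing_factor, config.smoothing_iterations
                )
                dmap = signed_vertex_distances(
                    model, phantom.ground_truth_mesh,
                    max_vertices=config.distance_map_vertices, seed=seed,
                )
                ssum = summarize(dmap)
                surface_rows.append(
                    dict(specimen=s, bone=bone, modality=modality,
                         mean_mm=ssum.mean, sd_mm=ssum.sd, n_vertices=ssum.n_vertices)
                )
                if out is not None and config.save_volumes:
                    vol_dir = out / f"specimen_{s:02d}" / modality
                    vol_dir.mkdir(parents=True, exist_ok=True)
                    write_volume(phantom.volume, vol_dir / f"{bone}.nii.gz")
                for location in LOCATIONS:
                    design = design_saw_guide(model, location, side=bone)
                    guide_lookup[(s, bone, location, modality)] = design
                    if out is not None and config.save_meshes:
                        mesh_dir = out / f"specimen_{s:02d}" / modality
                        mesh_dir.mkdir(parents=True, exist_ok=True)
                        write_stl(design.guide_mesh, mesh_dir / f"{bone}_{location}_guide.stl")
                if out is not None and config.save_meshes:
                    mesh_dir = out / f"specimen_{s:02d}" / modality
                    mesh_dir.mkdir(parents=True, exist_ok=True)
                    write_stl(model, mesh_dir / f"{bone}_model.stl")

    surface_comparison = pd.DataFrame(surface_rows)

    # ----- placements ------------------------------------------------------
    guides = sorted(guide_lookup.keys())
    # presentation order is shuffled per observer round, as in the original
    # protocol; numerically inert but recorded in the manifest
    shuffle_rng = np.random.default_rng(ss_shuffle.generate_state(1)[0] % (2**31))
    presentation = {}
    sessions = []
    for obs in range(1, config.n_observers + 1):
        sessions.append((obs, 0))
    if 1 <= config.repeat_observer <= config.n_observers:
        sessions.append((config.repeat_observer, 1))

    place_streams = iter(ss_place.spawn(len(sessions) * len(guides)))
    scan_streams = iter(ss_scan.spawn(len(sessions) * len(guides)))

    rows = []
    for obs, repeat in sessions:
        order = shuffle_rng.permutation(len(guides))
        presentation[f"observer_{obs}_session_{repeat}"] = [list(guides[i]) for i in order]
        for gi in order:
            s, bone, location, modality = guides[gi]
            design = guide_lookup[(s, bone, location, modality)]
            gt_mesh = ground_truth[(s, bone)]
            place_rng = np.random.default_rng(next(place_streams))
            scan_rng = np.random.default_rng(next(scan_streams))
            placed = simulate_placement(
                design.planned_box_pose, config.observer_error, place_rng
            )
            scan = simulate_optical_scan(gt_mesh, config.scan_noise, scan_rng)
            scan_box = placed.transformed(scan.true_offset)
            icp = dataclasses.replace(
                config.icp, seed=int(scan_rng.integers(2**31))
            )
            err, icp_result = placement_error_pipeline(
                gt_mesh, scan.mesh, scan_box, design, icp_params=icp
            )
            rows.append(
                dict(observer=obs, specimen=s, bone=bone, location=location,
                     modality=modality, repeat=repeat, **err.as_dict(),
                     icp_rms=icp_result.rms, converged=icp_result.converged)
            )

    records = gstats.records_frame(rows)

    # ----- statistics ------------------------------------------------------
    summary = gstats.summarize_by_modality(records)
    anova = {
        comp: gstats.rm_anova(records, comp) for comp in ("dT", "dR")
    }
    ba = {}
    for comp in ("dT", "dR"):
        wide = gstats.paired_modality_differences(records, comp)
        ba[comp] = gstats.bland_altman(
            wide["CT"].to_numpy(), wide["sCT"].to_numpy(),
            intra_pairs=gstats.intra_observer_pairs(records, comp),
            inter_deviations=gstats.observer_deviations(records, comp),
            inter_rule=config.inter_rule,
        )
    base = records[records["repeat"] == 0]
    outliers = base[["observer", "specimen", "bone", "location", "modality"]].copy()
    for comp in ("dT", "dR"):
        outliers[f"{comp}_outlier"] = gstats.flag_outliers(
            base[comp].abs().to_numpy(), base["observer"].to_numpy()
        )

    cfg = config.to_dict()
    manifest = {
        "seed": config.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "design": design_counts(config),
        "presentation_order": presentation,
        "runtime_s": round(time.time() - t_start, 1),
    }

    result = StudyResult(
        records=records, summary=summary, surface_comparison=surface_comparison,
        anova=anova, bland_altman=ba, outliers=outliers, manifest=manifest,
    )
    if out is not None:
        _write_bundle(result, out)
    return result


def _write_bundle(result: StudyResult, out: Path) -> None:
    result.records.to_csv(out / "placement_records.csv", index=False)
    result.summary.to_csv(out / "summary_by_modality.csv", index=False)
    result.surface_comparison.to_csv(out / "surface_comparison.csv", index=False)
    result.outliers.to_csv(out / "outlier_flags.csv", index=False)
    anova_rows = [
        dict(component=comp, effect=r.effect, F=r.F, df_num=r.df_num,
             df_den=r.df_den, p=r.p)
        for comp, results in result.anova.items()
        for r in results
    ]
    pd.DataFrame(anova_rows).to_csv(out / "anova.csv", index=False)
    ba_rows = []
    for comp, ba in result.bland_altman.items():
        ba_rows.append(
            dict(component=comp, mean_difference=ba.mean_difference,
                 loa_low=ba.loa_low, loa_high=ba.loa_high, intra_loa=ba.intra_loa,
                 inter_loa=ba.inter_loa,
                 fraction_within_inter_loa=ba.fraction_within_inter_loa,
                 fraction_within_intra_loa=ba.fraction_within_intra_loa,
                 equivalent=ba.equivalent, n=ba.n)
        )
        _bland_altman_plot(ba, comp, out / f"bland_altman_{comp}.png")
    pd.DataFrame(ba_rows).to_csv(out / "bland_altman.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)


def _bland_altman_plot(ba, component: str, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    unit = "mm" if component == "dT" else "deg"
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ba.means, ba.differences, s=18, color="k", zorder=3)
    ax.axhline(ba.mean_difference, color="grey", label=f"mean {ba.mean_difference:.2f}")
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="green", ls="--", lw=1)
    if np.isfinite(ba.intra_loa):
        for sgn in (-1, 1):
            ax.axhline(sgn * ba.intra_loa, color="purple", ls=":", lw=1)
    if np.isfinite(ba.inter_loa):
        for sgn in (-1, 1):
            ax.axhline(sgn * ba.inter_loa, color="red", ls="-.", lw=1)
    ax.set_xlabel(f"mean of CT and sCT {component} ({unit})")
    ax.set_ylabel(f"CT − sCT {component} ({unit})")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
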