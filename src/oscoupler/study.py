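"""Subject -> group orchestration and report rendering.

A :class:`StudyConfig` names every subject's EEG pair, BOLD NIfTI and
confound table, the grouping schemes (e.g. diagnosis and amyloid status),
the bands and regressor kinds to run, and the cluster/ALFF settings.
:func:`run_subject` takes one subject from raw EEG to per-band coupling
beta maps plus ALFF/mALFF; :func:`run_group` carries subject outputs to
cluster-corrected group tables (coupling F contrasts per band and regressor
kind; mALFF two-sample tests whole-brain and restricted to the union of
coupling-difference clusters); :func:`render_report` writes the tables as
TSV plus a markdown summary.

Between-group coupling differences are reported as undirected F contrasts
only — band-power/BOLD correlations are bidirectional, so a directional
between-group t-test would conflate stronger positive coupling with weaker
anticoupling.  Within-group one-sample t maps are emitted alongside to aid
interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alff import AlffConfig, AlffMaps, compute_alff, group_map_ttest, normalize_malff, residualize_motion
from .bands import get_band
from .cleaning import CleanConfig, clean_chain
from .cluster import (
    ClusterConfig,
    MonteCarloNull,
    monte_carlo_cluster_threshold,
    surviving_cluster_mask,
    threshold_clusters,
)
from .glm import (
    BoldRun,
    FirstLevelCoupling,
    GLMConfig,
    StatMap,
    group_fcontrast,
    group_onesample,
    smooth_volume,
)
from .recording import EEGRecording, read_eeg
from .spectral import regional_alpha, gsp, regressor_table, volume_spectra

__all__ = [
    "StudyConfig",
    "SubjectResult",
    "GroupReport",
    "run_subject",
    "run_subject_data",
    "run_group",
    "render_report",
]


@dataclass
class StudyConfig:
    """Declarative description of one study run."""

    subjects: dict[str, dict[str, str]]  # sid -> {eeg, bold, confounds}
    mask: str
    group_table: str                     # TSV: subject_id, <scheme columns>
    tr: float = 2.1
    bands: tuple[str, ...] = ("delta", "theta", "alpha1", "alpha2", "beta")
    regressor_kinds: tuple[str, ...] = ("GSP", "regional")
    smooth_fwhm: float = 8.0
    clean: CleanConfig = field(default_factory=CleanConfig)
    glm: GLMConfig = field(default_factory=GLMConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    alff: AlffConfig = field(default_factory=AlffConfig)
    out_dir: str = "oscoupler_out"
    seed: int = 0

    def validate_paths(self) -> None:
        missing = []
        for sid, paths in self.subjects.items():
            for key in ("bold", "confounds"):
                if key in paths and not Path(paths[key]).exists():
                    missing.append(f"{sid}:{key} -> {paths[key]}")
            if "eeg" in paths and not Path(paths["eeg"] + ".tsv").exists():
                missing.append(f"{sid}:eeg -> {paths['eeg']}.tsv")
        for p in (self.mask, self.group_table):
            if not Path(p).exists():
                missing.append(p)
        if missing:
            raise FileNotFoundError(
                "missing study inputs:\n  " + "\n  ".join(missing)
            )

    def labels(self, scheme: str) -> dict[str, str]:
        table = pd.read_csv(self.group_table, sep="\t", dtype=str)
        if scheme not in table.columns:
            raise KeyError(
                f"scheme {scheme!r} not in group table columns {list(table.columns)}"
            )
        labels = dict(zip(table["subject_id"], table[scheme]))
        levels = sorted(set(labels.values()))
        if len(levels) != 2:
            raise ValueError(
                f"scheme {scheme!r} must have exactly two groups, got {levels}"
            )
        return labels

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key, klass in [
            ("clean", CleanConfig),
            ("glm", GLMConfig),
            ("cluster", ClusterConfig),
            ("alff", AlffConfig),
        ]:
            if key in raw and isinstance(raw[key], dict):
                for tup in ("bandpass", "band_reject", "band"):
                    if tup in raw[key]:
                        raw[key][tup] = tuple(raw[key][tup])
                raw[key] = klass(**raw[key])
        for tup_key in ("bands", "regressor_kinds"):
            if tup_key in raw:
                raw[tup_key] = tuple(raw[tup_key])
        return cls(**raw)


@dataclass
class SubjectResult:
    subject_id: str
    beta_maps: dict[tuple[str, str], StatMap]  # (band, kind) -> interest beta
    alff: AlffMaps
    regressors: pd.DataFrame
    rho: dict[tuple[str, str], float] = field(default_factory=dict)


def run_subject_data(
    cfg: StudyConfig,
    subject_id: str,
    eeg: EEGRecording,
    bold: BoldRun,
    bad_epochs: list[int] | None = None,
) -> SubjectResult:
    """First-level pipeline on in-memory data: clean EEG, build per-band
    regressors, fit the coupling GLM per (band, kind), compute ALFF/mALFF."""
    clean = clean_chain(eeg, cfg.clean, bad_epochs)
    spectra = volume_spectra(clean, cfg.tr)
    smoothed = smooth_volume(bold, cfg.smooth_fwhm)

    series_list = []
    beta_maps: dict[tuple[str, str], StatMap] = {}
    rho: dict[tuple[str, str], float] = {}
    for band_name in cfg.bands:
        band = get_band(band_name)
        for kind in cfg.regressor_kinds:
            if kind == "GSP":
                series = gsp(spectra, band)
            elif kind == "regional":
                series = regional_alpha(spectra, band=band)
            else:
                raise ValueError(f"unknown regressor kind {kind!r}")
            series_list.append(series)
            res = FirstLevelCoupling(smoothed, series, cfg.glm).fit()
            bmap = res.beta_map("interest")
            bmap.provenance.update(
                {"band": band_name, "kind": kind, "subject": subject_id}
            )
            beta_maps[(band_name, kind)] = bmap
            rho[(band_name, kind)] = res.rho

    resid = residualize_motion(smoothed)
    maps = normalize_malff(compute_alff(resid, cfg.alff))
    return SubjectResult(
        subject_id=subject_id,
        beta_maps=beta_maps,
        alff=maps,
        regressors=regressor_table(series_list),
        rho=rho,
    )


def run_subject(cfg: StudyConfig, subject_id: str) -> SubjectResult:
    """Path-based wrapper around :func:`run_subject_data`."""
    try:
        paths = cfg.subjects[subject_id]
    except KeyError:
        raise KeyError(f"subject {subject_id!r} not in the study config") from None
    for key in ("eeg", "bold", "confounds"):
        if key not in paths:
            raise FileNotFoundError(f"subject {subject_id}: no {key!r} path configured")
    eeg = read_eeg(paths["eeg"])
    bold = BoldRun.from_files(paths["bold"], cfg.mask, paths["confounds"], tr=cfg.tr)
    return run_subject_data(cfg, subject_id, eeg, bold)


@dataclass
class GroupReport:
    scheme: str
    coupling_f: dict[tuple[str, str], StatMap]
    coupling_tables: dict[tuple[str, str], pd.DataFrame]
    within_t: dict[tuple[str, str, str], StatMap]  # (band, kind, group)
    malff_t: StatMap
    malff_table: pd.DataFrame
    malff_restricted_t: StatMap | None
    malff_restricted_table: pd.DataFrame | None
    restrict_mask: np.ndarray
    null: MonteCarloNull


def run_group(
    cfg: StudyConfig,
    results: dict[str, SubjectResult],
    scheme: str = "group",
) -> GroupReport:
    """Second-level inference for one grouping scheme.

    Coupling: undirected F contrast per (band, kind) with Monte-Carlo
    cluster correction (one null simulation per analysis mask).  mALFF:
    two-sample t, whole-brain and restricted to the union of all
    coupling-difference clusters across bands and kinds.
    """
    labels_by_sid = cfg.labels(scheme)
    sids = [s for s in results if s in labels_by_sid]
    if len(sids) < 4:
        raise ValueError("need at least two subjects per group")
    groups = np.asarray([labels_by_sid[s] for s in sids])
    for level in pd.unique(groups):
        if (groups == level).sum() < 2:
            raise ValueError(f"group {level!r} has fewer than two subjects")

    first = results[sids[0]]
    mask = first.alff.mask
    voxel = float(np.abs(np.linalg.det(first.alff.affine[:3, :3])) ** (1 / 3))
    null = monte_carlo_cluster_threshold(mask, cfg.cluster, voxel)

    coupling_f: dict[tuple[str, str], StatMap] = {}
    coupling_tables: dict[tuple[str, str], pd.DataFrame] = {}
    within_t: dict[tuple[str, str, str], StatMap] = {}
    union = np.zeros(mask.shape, dtype=bool)
    for key in first.beta_maps:
        maps = [results[s].beta_maps[key] for s in sids]
        fmap = group_fcontrast(maps, groups)
        fmap.provenance.update({"band": key[0], "kind": key[1], "scheme": scheme})
        coupling_f[key] = fmap
        coupling_tables[key] = threshold_clusters(fmap, null, cfg.cluster)
        union |= surviving_cluster_mask(fmap, null, cfg.cluster)
        for level in pd.unique(groups):
            sub = [results[s].beta_maps[key] for s in sids if labels_by_sid[s] == level]
            tmap = group_onesample(sub)
            tmap.provenance.update(
                {"band": key[0], "kind": key[1], "group": str(level)}
            )
            within_t[(key[0], key[1], str(level))] = tmap

    alff_maps = [results[s].alff for s in sids]
    malff_t, malff_table = group_map_ttest(
        alff_maps, groups, cfg.cluster, voxel_size_mm=voxel
    )
    if union.any():
        r_t, r_table = group_map_ttest(
            alff_maps, groups, cfg.cluster, restrict_mask=union, voxel_size_mm=voxel
        )
    else:
        r_t, r_table = None, None
    return GroupReport(
        scheme=scheme,
        coupling_f=coupling_f,
        coupling_tables=coupling_tables,
        within_t=within_t,
        malff_t=malff_t,
        malff_table=malff_table,
        malff_restricted_t=r_t,
        malff_restricted_table=r_table,
        restrict_mask=union,
        null=null,
    )


def render_report(report: GroupReport, out_dir: str | Path) -> Path:
    """Write cluster tables as TSV and a markdown summary; returns the
    markdown path.  Tables keep a fixed column order and round-trip via
    ``pd.read_csv(..., sep='\\t')``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = [
        f"# EEG-fMRI coupling report — scheme `{report.scheme}`",
        "",
        f"Cluster-extent threshold k_min = {report.null.k_min} voxels "
        f"(alpha {report.null.config.alpha_cluster}, voxel p "
        f"{report.null.config.voxel_p}, {report.null.config.n_iter} iterations, "
        f"{report.null.n_mask_voxels} mask voxels).",
        "",
        "## Between-group coupling differences (undirected F)",
        "",
    ]
    any_rows = False
    for (band, kind), table in sorted(report.coupling_tables.items()):
        stem = f"coupling_{report.scheme}_{band}_{kind}"
        table.to_csv(out / f"{stem}.tsv", sep="\t", index=False)
        if len(table):
            any_rows = True
            lines.append(f"### {band} / {kind}")
            lines.append("")
            lines.append(table.to_markdown(index=False))
            lines.append("")
    if not any_rows:
        lines.append("No clusters survived correction.")
        lines.append("")

    lines += ["## mALFF group differences (two-sample t)", ""]
    report.malff_table.to_csv(
        out / f"malff_{report.scheme}_wholebrain.tsv", sep="\t", index=False
    )
    lines.append("### Whole brain")
    lines.append("")
    lines.append(
        report.malff_table.to_markdown(index=False)
        if len(report.malff_table)
        else "No clusters survived correction."
    )
    lines.append("")
    if report.malff_restricted_table is not None:
        report.malff_restricted_table.to_csv(
            out / f"malff_{report.scheme}_restricted.tsv", sep="\t", index=False
        )
        lines.append("### Restricted to coupling-difference mask")
        lines.append("")
        lines.append(
            report.malff_restricted_table.to_markdown(index=False)
            if len(report.malff_restricted_table)
            else "No clusters survived correction."
        )
        lines.append("")
    md = out / f"report_{report.scheme}.md"
    md.write_text("\n".join(lines))
    return md
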