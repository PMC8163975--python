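"""End-to-end drivers: manifest + alignments -> matrix artifacts; CSVs -> fit report.

The matrix pipeline reads a YAML manifest naming, per complex, the
structure file, the GTPase and effector chains and the effector family,
projects each complex's contacts through the alignment maps and writes
the interaction matrix, hotspot and conservation reports.  The affinity
pipeline fits a batch of titration CSVs and writes a per-pair report
with affinity bands.  Both are deterministic for fixed inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import affinity as aff
from . import alignment as aln
from . import matrix as mx
from . import structure as struct

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "PipelineError",
    "ConfigError",
    "run_matrix_pipeline",
    "run_affinity_pipeline",
]


class PipelineError(RuntimeError):
    """A data-level failure naming the offending complex or file."""


class ConfigError(ValueError):
    """An invalid or incomplete run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one matrix-pipeline run."""

    manifest: Path
    gtpase_alignment: Path
    effector_alignment: Path
    gtpase_reference: str
    effector_reference: str
    gtpase_start: int = 1
    effector_start: int = 1
    cutoff: float = struct.DEFAULT_CUTOFF
    min_support: int | None = None          # None -> ceil(n_complexes / 2)
    conservation_threshold: float = aln.DEFAULT_CONSERVATION_THRESHOLD
    out_dir: Path = Path("raseff_out")
    seed: int = 0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ConfigError(f"cutoff must be > 0, got {self.cutoff}")
        for p in (self.manifest, self.gtpase_alignment, self.effector_alignment):
            if not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(path).parent
        for key in ("manifest", "gtpase_alignment", "effector_alignment",
                    "out_dir"):
            if key in raw:
                raw[key] = base / raw[key]
        raw.update({k: v for k, v in overrides.items() if v is not None})
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"manifest", "gtpase_alignment", "effector_alignment",
                   "gtpase_reference", "effector_reference"} - set(raw)
        if missing:
            raise ConfigError(f"missing config keys: {sorted(missing)}")
        return cls(**raw)


def _load_manifest(path: Path) -> list[dict]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    entries = raw.get("complexes", [])
    if not entries:
        raise PipelineError(f"{path}: no complexes in manifest")
    required = {"complex_id", "path", "gtpase_chain", "effector_chain",
                "effector_family"}
    out = []
    for e in entries:
        missing = required - set(e)
        if missing:
            raise PipelineError(
                f"{path}: manifest entry {e.get('complex_id', '?')!r} "
                f"missing {sorted(missing)}"
            )
        e = dict(e)
        e["path"] = str(Path(path).parent / e["path"])
        out.append(e)
    ids = [e["complex_id"] for e in out]
    if len(set(ids)) != len(ids):
        raise PipelineError(f"{path}: duplicate complex ids")
    return out


def _contact_table(contacts) -> pd.DataFrame:
    rows = [
        {
            "gtpase_chain": c.gtpase_residue.chain,
            "gtpase_resnum": c.gtpase_residue.seq_number,
            "gtpase_aa": c.gtpase_residue.aa,
            "effector_chain": c.effector_residue.chain,
            "effector_resnum": c.effector_residue.seq_number,
            "effector_aa": c.effector_residue.aa,
            "min_distance_A": round(c.min_distance, 3),
        }
        for c in sorted(
            contacts,
            key=lambda c: (c.gtpase_residue.seq_number,
                           c.effector_residue.seq_number),
        )
    ]
    return pd.DataFrame(
        rows,
        columns=["gtpase_chain", "gtpase_resnum", "gtpase_aa",
                 "effector_chain", "effector_resnum", "effector_aa",
                 "min_distance_A"],
    )


def run_matrix_pipeline(config: RunConfig) -> mx.InteractionMatrix:
    """Run contacts -> mapping -> matrix -> hotspots and write artifacts.

    Writes, under ``config.out_dir``: per-complex ``contacts_<id>.tsv``,
    ``interaction_matrix.tsv``/``.json``, ``hotspots.tsv`` (both axes,
    with conservation labels) and ``conservation.tsv``.  Any stage
    failure aborts the run, removes partial outputs and raises
    :class:`PipelineError` naming the complex.
    """
    entries = _load_manifest(Path(config.manifest))
    g_aln = aln.read_alignment(config.gtpase_alignment,
                               reference_row=config.gtpase_reference)
    e_aln = aln.read_alignment(config.effector_alignment,
                               reference_row=config.effector_reference)
    g_labels = aln.reference_labels(g_aln, config.gtpase_start)
    e_labels = aln.reference_labels(e_aln, config.effector_start)

    out = Path(config.out_dir)
    fresh = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        contacts_per_complex = {}
        g_maps = {}
        e_maps = {}
        for entry in entries:
            cid = entry["complex_id"]
            try:
                spec = struct.ComplexSpec(
                    complex_id=cid,
                    source_path=entry["path"],
                    gtpase_chain=entry["gtpase_chain"],
                    effector_chain=entry["effector_chain"],
                    effector_family=entry["effector_family"],
                    model_index=int(entry.get("model_index", 0)),
                )
                st = struct.read_structure(spec.source_path)
                contacts = struct.extract_contacts(
                    spec, structure=st, cutoff=config.cutoff
                )
                g_row = entry.get("gtpase_row", config.gtpase_reference)
                e_row = entry.get("effector_row", config.effector_reference)
                g_map = aln.map_chain_to_row(
                    struct.chain_residue_refs(st, spec.gtpase_chain,
                                              spec.model_index),
                    g_aln.row(g_row), cid, g_row,
                )
                e_map = aln.map_chain_to_row(
                    struct.chain_residue_refs(st, spec.effector_chain,
                                              spec.model_index),
                    e_aln.row(e_row), cid, e_row,
                )
            except (ValueError, FileNotFoundError, KeyError) as exc:
                raise PipelineError(f"complex {cid!r}: {exc}") from exc
            contacts_per_complex[cid] = contacts
            g_maps[cid] = g_map.as_dict()
            e_maps[cid] = e_map.as_dict()
            if g_map.unmapped or e_map.unmapped:
                logger.warning(
                    "%s: %d GTPase / %d effector residues unmapped",
                    cid, len(g_map.unmapped), len(e_map.unmapped),
                )
            p = out / f"contacts_{cid}.tsv"
            _contact_table(contacts).to_csv(p, sep="\t", index=False)
            written.append(p)

        matrix = mx.build_matrix(
            contacts_per_complex, g_maps, e_maps, g_labels, e_labels
        )
        min_support = (config.min_support if config.min_support is not None
                       else mx.default_min_support(matrix.n_complexes))
        g_cons = aln.classify_columns(g_aln, threshold=config.conservation_threshold)
        e_cons = aln.classify_columns(e_aln, threshold=config.conservation_threshold)

        matrix.to_tsv(out / "interaction_matrix.tsv")
        matrix.to_json(out / "interaction_matrix.json")
        written += [out / "interaction_matrix.tsv", out / "interaction_matrix.json"]

        hotspots = (
            mx.hotspot_residues(matrix, "gtpase", min_support, g_cons)
            + mx.hotspot_residues(matrix, "effector", min_support, e_cons)
        )
        pd.DataFrame(
            [dataclasses.asdict(h) for h in hotspots],
            columns=["axis", "label", "support", "conservation"],
        ).to_csv(out / "hotspots.tsv", sep="\t", index=False)
        written.append(out / "hotspots.tsv")

        cons_rows = []
        for axis, labels, cons in (("gtpase", g_labels, g_cons),
                                   ("effector", e_labels, e_cons)):
            for i, lab in enumerate(labels.labels):
                cons_rows.append(
                    {"axis": axis, "column": i, "label": lab, "call": cons[i]}
                )
        pd.DataFrame(cons_rows).to_csv(out / "conservation.tsv", sep="\t",
                                       index=False)
        written.append(out / "conservation.tsv")
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        if fresh and not any(out.iterdir()):
            shutil.rmtree(out, ignore_errors=True)
        raise
    return matrix


def run_affinity_pipeline(
    titration_files,
    out_dir,
    receptor_total: float = 1.0,
    comparisons: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Fit a batch of titration CSVs; returns (report table, n_failed_files).

    Unreadable files are reported and skipped; the run continues and the
    failure count is returned so callers can set a nonzero exit status.
    Writes ``fit_report.tsv``, ``band_summary.tsv`` and, when
    comparisons are requested, ``comparisons.tsv``.
    """
    files = list(titration_files)
    if not files:
        raise PipelineError("no titration files given")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    fits = {}
    n_failed = 0
    for f in files:
        try:
            data = aff.read_titration_csv(f, receptor_total=receptor_total)
            fit = aff.fit_titration(data)
        except (ValueError, OSError) as exc:
            logger.error("%s: %s", f, exc)
            n_failed += 1
            continue
        fits[fit.label] = fit
        rows.append(
            {
                "label": fit.label,
                "kd_uM": fit.kd,
                "kd_se_uM": fit.kd_se,
                "p_free": fit.p_free,
                "p_bound": fit.p_bound,
                "rss": fit.rss,
                "band": fit.affinity_band,
                "converged": fit.converged,
            }
        )
    report = pd.DataFrame(
        rows, columns=["label", "kd_uM", "kd_se_uM", "p_free", "p_bound",
                       "rss", "band", "converged"],
    ).sort_values("label").reset_index(drop=True)
    report.to_csv(out / "fit_report.tsv", sep="\t", index=False)

    bands = report["band"].value_counts().rename_axis("band").reset_index(name="count")
    bands.to_csv(out / "band_summary.tsv", sep="\t", index=False)

    if comparisons:
        comp_rows = []
        for label_a, label_b in comparisons:
            try:
                cmp_res = aff.compare_fits(fits[label_a], fits[label_b])
            except (KeyError, ValueError) as exc:
                logger.error("comparison %s vs %s: %s", label_a, label_b, exc)
                n_failed += 1
                continue
            comp_rows.append(
                {
                    "label_a": label_a,
                    "label_b": label_b,
                    "fold_change": cmp_res.fold_change,
                    "z": cmp_res.z,
                    "p_value": cmp_res.p_value,
                }
            )
        pd.DataFrame(
            comp_rows,
            columns=["label_a", "label_b", "fold_change", "z", "p_value"],
        ).to_csv(out / "comparisons.tsv", sep="\t", index=False)
    return report, n_failed
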