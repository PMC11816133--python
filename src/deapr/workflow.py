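"""End-to-end pipeline: comparisons, set algebra, patterns, variability,
pathway ranking, driven by one config document.

The pipeline is a pure function of (input files, parameters): re-running an
identical config writes byte-identical data tables.  A run manifest (tool
version, input digests, parameters, timestamp) is written alongside the
outputs so a run can be audited and reproduced.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .compare import (
    classify_dose_patterns,
    intersect_comparisons,
    specific_genes,
    write_common,
    write_patterns,
)
from .core import (
    DEFAULT_FLOOR,
    DEFAULT_MIN_FPKM,
    ComparisonResult,
    select_de_genes,
)
from .errors import ValidationError
from .matrix import (
    load_sample_sets,
    read_expression_table,
    read_gene_annotation,
    sets_by_label,
)
from .pathways import (
    DEFAULT_TOP_N,
    adjust_by_rank,
    overrepresentation_score,
    read_gmt,
    select_top_n,
    write_pathways,
)
from .variability import CODING, NON_CODING, variability_profile, write_profiles

logger = logging.getLogger(__name__)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require_file(path: str | None, what: str) -> Path:
    if path is None:
        raise ValidationError(f"config is missing required entry {what!r}")
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"{what} file not found: {p}")
    return p


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValidationError(f"workflow config {path} must be a mapping")
    return doc


def run_workflow(config: Mapping[str, Any], out_dir: str | Path) -> Path:
    """Execute the configured pipeline and write all outputs under out_dir.

    Config keys: ``matrix``, ``annotation``, ``sets`` (paths);
    ``comparisons`` (name -> {ref, test}); optional ``common``
    (name -> {a, b}), ``specific`` (name -> {of, common}), ``patterns``
    ({comparison, low, mid, high, tolerance}), ``variability``
    ({sets: [labels] | "all"}), ``pathways`` ({gmt, comparisons, top_n,
    weights}); scalars ``floor``, ``min_fpkm``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix_path = _require_file(config.get("matrix"), "matrix")
    annotation_path = _require_file(config.get("annotation"), "annotation")
    sets_path = _require_file(config.get("sets"), "sets")
    floor = float(config.get("floor", DEFAULT_FLOOR))
    min_fpkm = float(config.get("min_fpkm", DEFAULT_MIN_FPKM))

    matrix = read_expression_table(str(matrix_path))
    annotation = read_gene_annotation(str(annotation_path))
    sets = sets_by_label(load_sample_sets(str(sets_path)))

    digests = {p.name: _digest(p) for p in (matrix_path, annotation_path, sets_path)}

    def get_set(label: str):
        if label not in sets:
            raise ValidationError(f"unknown sample-set label {label!r}")
        return sets[label]

    comparisons: dict[str, ComparisonResult] = {}
    comp_cfg = config.get("comparisons") or {}
    for name, pair in comp_cfg.items():
        logger.info("comparison %s: %s vs %s", name, pair["ref"], pair["test"])
        result = select_de_genes(
            matrix, annotation, get_set(pair["ref"]), get_set(pair["test"]),
            floor=floor, min_fpkm=min_fpkm,
        )
        comparisons[name] = result
        result.to_tsv(str(out / f"{name}.tsv"), matrix)

    def get_comparison(name: str) -> ComparisonResult:
        if name not in comparisons:
            raise ValidationError(f"unknown comparison name {name!r}")
        return comparisons[name]

    commons: dict[str, list] = {}
    for name, pair in (config.get("common") or {}).items():
        common = intersect_comparisons(get_comparison(pair["a"]), get_comparison(pair["b"]))
        commons[name] = common
        write_common(common, str(out / f"{name}_common.tsv"))

    for name, entry in (config.get("specific") or {}).items():
        if entry["common"] not in commons:
            raise ValidationError(f"unknown common-list name {entry['common']!r}")
        specific = specific_genes(get_comparison(entry["of"]), commons[entry["common"]])
        comparisons[name] = specific
        specific.to_tsv(str(out / f"{name}_specific.tsv"), matrix)

    pat_cfg = config.get("patterns")
    if pat_cfg:
        patterns = classify_dose_patterns(
            matrix,
            get_comparison(pat_cfg["comparison"]),
            get_set(pat_cfg["low"]), get_set(pat_cfg["mid"]), get_set(pat_cfg["high"]),
            tolerance=float(pat_cfg.get("tolerance", 1.25)),
            floor=floor,
        )
        write_patterns(patterns, str(out / "dose_patterns.tsv"))

    var_cfg = config.get("variability")
    if var_cfg:
        labels = var_cfg.get("sets", "all")
        if labels == "all":
            labels = list(sets)
        profiles = [
            variability_profile(matrix, annotation, get_set(label),
                                biotype_class=bc, min_fpkm=min_fpkm, floor=floor)
            for label in labels
            for bc in (CODING, NON_CODING)
        ]
        write_profiles(profiles, str(out / "variability.tsv"))

    pw_cfg = config.get("pathways")
    if pw_cfg:
        gmt_path = _require_file(pw_cfg.get("gmt"), "pathways.gmt")
        digests[gmt_path.name] = _digest(gmt_path)
        collection = read_gmt(str(gmt_path))
        top_n = int(pw_cfg.get("top_n", DEFAULT_TOP_N))
        scheme = pw_cfg.get("weights", "linear")
        for comp_name in pw_cfg.get("comparisons", []):
            submitted = select_top_n(get_comparison(comp_name), n=top_n)
            scored = overrepresentation_score(submitted, collection)
            adjusted = adjust_by_rank(scored, submitted, scheme=scheme)
            write_pathways(adjusted, str(out / f"{comp_name}_pathways.tsv"))

    manifest = {
        "tool_version": __version__,
        "input_digests": digests,
        "parameters": {
            "floor": floor,
            "min_fpkm": min_fpkm,
            "comparisons": {k: dict(v) for k, v in comp_cfg.items()},
            "patterns": dict(pat_cfg) if pat_cfg else None,
            "pathways": {k: v for k, v in pw_cfg.items()} if pw_cfg else None,
        },
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
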