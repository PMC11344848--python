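"""Run configuration and report assembly for panel comparisons.

``run_comparison`` ties the pipeline together: it resolves two peptide
panels (from FASTA paths or generator specs), runs the requested
similarity methods, and writes a diff-able report bundle:

* one similarity-matrix TSV per method;
* a positional-profile TSV (pair, position, value) for every cross-family
  pair, when all peptides share one length — otherwise the positional
  method is skipped with a logged message and the others proceed;
* per-method PanelComparison JSON of per-peptide cross/within means
  (self-comparisons excluded);
* ``manifest.json`` recording panels, parameters, seed, methods and
  package version, from which the bundle regenerates bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .chem import Peptide
from .fingerprints import FingerprintParams
from .panels import PanelSpec, generate_panel, read_fasta
from .similarity import (
    METHODS,
    cross_family_averages,
    pairwise_matrix,
    positional_similarity,
)

logger = logging.getLogger("pepsim")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one comparison run."""

    panel_a: str | PanelSpec  # FASTA path or generator spec
    panel_b: str | PanelSpec
    methods: tuple[str, ...] = METHODS
    params: FingerprintParams = field(default_factory=FingerprintParams)
    exact: bool = False
    output_dir: str = "pepsim_report"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one method is required")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        for key in ("panel_a", "panel_b"):
            if isinstance(raw.get(key), dict):
                raw[key] = PanelSpec(**raw[key])
        if isinstance(raw.get("params"), dict):
            raw["params"] = FingerprintParams(**raw["params"])
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)


def _resolve_panel(source: str | PanelSpec, seed_shift: int, seed: int) -> list[Peptide]:
    if isinstance(source, PanelSpec):
        spec = dataclasses.replace(source, seed=(source.seed + seed + seed_shift) % 2**31)
        return generate_panel(spec)
    return read_fasta(source)


def _panel_manifest(source: str | PanelSpec) -> dict | str:
    if isinstance(source, PanelSpec):
        return dataclasses.asdict(source)
    return str(source)


def run_comparison(config: RunConfig) -> dict[str, list[str]]:
    """Execute a comparison run; returns the emitted files per method."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel_a = _resolve_panel(config.panel_a, 0, config.seed)
    panel_b = _resolve_panel(config.panel_b, 1, config.seed)
    panel = panel_a + panel_b
    ids_a = [p.id for p in panel_a]
    ids_b = [p.id for p in panel_b]

    lengths = {len(p) for p in panel}
    emitted: dict[str, list[str]] = {}
    methods_run: list[str] = []
    for method in config.methods:
        if method == "positional_mean" and len(lengths) != 1:
            logger.warning(
                "skipping positional method: unequal peptide lengths %s",
                sorted(lengths),
            )
            continue
        files: list[str] = []
        matrix = pairwise_matrix(panel, method, config.params, exact=config.exact)
        matrix_path = out / f"similarity_{method}.tsv"
        matrix.to_tsv(matrix_path)
        files.append(matrix_path.name)

        comparison = cross_family_averages(matrix, ids_a, ids_b)
        comp_path = out / f"comparison_{method}.json"
        comp_path.write_text(comparison.to_json() + "\n")
        files.append(comp_path.name)

        if method == "positional_mean":
            prof_path = out / "positional_profiles.tsv"
            with open(prof_path, "w") as handle:
                handle.write("id_a\tid_b\tposition\tsimilarity\n")
                for pa in panel_a:
                    for pb in panel_b:
                        profile = positional_similarity(
                            pa, pb, config.params, exact=config.exact
                        )
                        for pos, val in zip(profile.positions, profile.values):
                            handle.write(f"{pa.id}\t{pb.id}\t{pos}\t{val:.6f}\n")
            files.append(prof_path.name)
        emitted[method] = files
        methods_run.append(method)

    manifest = {
        "tool": "pepsim",
        "version": __version__,
        "seed": config.seed,
        "exact": config.exact,
        "params": dataclasses.asdict(config.params),
        "panel_a": _panel_manifest(config.panel_a),
        "panel_b": _panel_manifest(config.panel_b),
        "methods_requested": list(config.methods),
        "methods_run": methods_run,
        "files": emitted,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return emitted
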