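"""Plain-text table I/O, dataset emission and manifests.

All tables are tab-separated with a single header row; floats are
written with full ``repr`` precision so a write/read round trip
reproduces values exactly. The dataset manifest is JSON and records the
configuration, seed and a sha256 checksum per file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Mapping, Optional

import pandas as pd
import yaml

from .errors import ConfigurationError, SchemaError
from .scheme import FractionScheme

MANIFEST_NAME = "manifest.json"


def write_tsv(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path, required_columns=()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in required_columns if c not in table.columns]
    if missing:
        raise SchemaError(f"{path} is missing columns: {missing}")
    return table


def read_protein_fractions(path) -> pd.DataFrame:
    return read_tsv(path, ("protein_id", "fraction_id", "condition",
                           "channel", "abundance"))


def read_tmt(path) -> pd.DataFrame:
    return read_tsv(path, ("protein_id", "sample_id", "condition",
                           "perturbation", "intensity"))


def read_fraction_fpkm(path) -> pd.DataFrame:
    return read_tsv(path, ("gene_id", "sample_id", "fraction_id", "fpkm"))


def read_scheme(path) -> FractionScheme:
    """Read a fraction scheme from a YAML mapping."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return FractionScheme.from_dict(data)


def write_scheme(scheme: FractionScheme, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(scheme.to_dict(), fh, sort_keys=False)
    return path


def read_set_file(path) -> Dict[str, frozenset]:
    """Read a one-identifier-per-line set file; the header is the set name."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    lines = [l.strip() for l in path.read_text().splitlines() if l.strip()]
    if not lines:
        raise SchemaError(f"{path} is empty")
    return {lines[0]: frozenset(lines[1:])}


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def emit_dataset(tables: Mapping[str, pd.DataFrame], output_directory,
                 config: Optional[Mapping] = None,
                 seed: Optional[int] = None) -> dict:
    """Write every table as ``<name>.tsv`` plus a JSON manifest.

    The manifest records the config, seed and per-file sha256 checksums;
    rewriting an identical table leaves its checksum unchanged. The
    output directory must already exist.
    """
    outdir = Path(output_directory)
    if not outdir.is_dir():
        raise ConfigurationError(f"output directory does not exist: {outdir}")
    files = {}
    for name, table in tables.items():
        p = write_tsv(table, outdir / f"{name}.tsv")
        files[f"{name}.tsv"] = {"sha256": sha256_of(p), "rows": int(len(table))}
    manifest = {
        "config": dict(config) if config else {},
        "seed": seed,
        "files": files,
    }
    with open(outdir / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def read_manifest(output_directory) -> dict:
    p = Path(output_directory) / MANIFEST_NAME
    if not p.exists():
        raise ConfigurationError(f"no manifest at {p}")
    with open(p) as fh:
        return json.load(fh)
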