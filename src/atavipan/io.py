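"""File formats: provenance-headed TSV, GMT gene sets, YAML manifests.

All tabular outputs are TSV with '#'-prefixed provenance header lines
(package version, seed, thresholds) that readers skip; no timestamps are
written, so identical runs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from . import __version__


def write_tsv(df: pd.DataFrame, path, provenance: dict | None = None,
              index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# atavipan {__version__}"]
    for k, v in (provenance or {}).items():
        lines.append(f"# {k}: {v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene-set reader: name <tab> description <tab> members..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "synthetic") -> None:
    lines = [
        "\t".join([name, description] + list(members))
        for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
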