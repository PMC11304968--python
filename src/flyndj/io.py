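"""TSV readers/writers, flat config parsing and run manifests.

All tabular interchange uses one dialect: tab-delimited, UTF-8, header
row, '.' decimal — the format progeny tallies and genotyping sheets are
hand-curated in.  Haplotypes travel as fixed-width 'm'/'+' codes over the
scored loci.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .crosses import NDJCounts
from .markers import MarkerMap
from .meiosis import OvaTable, SimConfig
from .recomb import DiploXRecord

__all__ = [
    "read_counts_table",
    "write_counts_table",
    "read_screen_manifest",
    "write_screen_manifest",
    "read_diplox_records",
    "write_diplox_records",
    "read_sons_table",
    "write_sons_table",
    "read_sim_config",
    "write_sim_config",
    "write_ova_table",
    "RunManifest",
]

_COUNT_COLS = ("n_normal", "e_diploX", "e_XY")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _require(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _counts_from_row(row, path, line_no: int) -> NDJCounts:
    vals = []
    for col in _COUNT_COLS:
        raw = row[col]
        try:
            v = int(raw)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}, row {line_no}: {col} = {raw!r} is not an integer"
            ) from None
        if v < 0:
            raise ValueError(f"{path}, row {line_no}: {col} = {v} is negative")
        vals.append(v)
    return NDJCounts(*vals)


def read_counts_table(path) -> list[tuple[str, str, NDJCounts]]:
    """Read (cross_id, genotype_arm, counts) rows from a progeny-tally TSV."""
    df = _read_tsv(path)
    _require(df, ("cross_id", "genotype_arm") + _COUNT_COLS, path)
    out = []
    for i, row in enumerate(df.to_dict("records"), start=2):
        out.append(
            (row["cross_id"], row["genotype_arm"], _counts_from_row(row, path, i))
        )
    return out


def write_counts_table(rows: Sequence[tuple[str, str, NDJCounts]], path) -> None:
    pd.DataFrame(
        [
            {
                "cross_id": cid,
                "genotype_arm": arm,
                "n_normal": c.n_normal,
                "e_diploX": c.e_diploX,
                "e_XY": c.e_XY,
            }
            for cid, arm, c in rows
        ]
    ).to_csv(path, sep="\t", index=False)


def read_screen_manifest(path) -> pd.DataFrame:
    """Screen manifest: gene, arm, n_normal, e_diploX, e_XY (one row per arm)."""
    df = _read_tsv(path)
    _require(df, ("gene", "arm") + _COUNT_COLS, path)
    for i, row in enumerate(df.to_dict("records"), start=2):
        _counts_from_row(row, path, i)  # validates
    for col in _COUNT_COLS:
        df[col] = df[col].astype(int)
    return df


def write_screen_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def write_diplox_records(records: Sequence[DiploXRecord], path) -> None:
    """One row per Diplo-X female: phenotype, sons, and analysis columns."""
    rows = []
    n_sons = max((len(r.sons) for r in records), default=0)
    for r in records:
        row = {"female_id": r.female_id, "phenotype": r.phenotype}
        for j in range(n_sons):
            row[f"son{j + 1}"] = r.sons[j] if j < len(r.sons) else ""
        row.update(
            chromatid1=r.pair[0],
            chromatid2=r.pair[1],
            confidence=r.confidence,
            error_type=r.error_type,
            recombinant1=int(r.recomb_flags[0]),
            recombinant2=int(r.recomb_flags[1]),
            note=r.note,
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_diplox_records(path) -> list[tuple[str, str, list[str]]]:
    """Read raw genotyping sheets: (female_id, phenotype, son codes).

    Son columns are every column whose name starts with 'son'; empty cells
    mean fewer sons for that female.
    """
    df = _read_tsv(path)
    _require(df, ("female_id", "phenotype"), path)
    son_cols = [c for c in df.columns if c.startswith("son")]
    if not son_cols:
        raise ValueError(f"{path}: no son columns (son1, son2, ...)")
    out = []
    for row in df.to_dict("records"):
        sons = [row[c] for c in son_cols if row[c]]
        out.append((row["female_id"], row["phenotype"], sons))
    return out


def read_sons_table(path) -> list[str]:
    """Read the crossover-frequency assay's son list (column 'haplotype')."""
    df = _read_tsv(path)
    _require(df, ("haplotype",), path)
    return [h for h in df["haplotype"] if h]


def write_sons_table(sons: Sequence[str], path) -> None:
    pd.DataFrame({"haplotype": list(sons)}).to_csv(path, sep="\t", index=False)


# -- simulation config ---------------------------------------------------

_SIMPLE_KEYS = (
    "p_arm_loss",
    "p_mii_loss",
    "backup_enabled",
    "backup_efficiency",
    "obligate_chiasma",
    "n_oocytes",
    "seed",
)


def read_sim_config(path) -> SimConfig:
    """Parse a flat key: value simulation config.

    Recognised keys are the SimConfig fields; the map can be overridden
    with ``loci`` / ``interval_r`` / ``scored_loci`` comma lists.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected flat key: value pairs")
    known = set(_SIMPLE_KEYS) | {"loci", "interval_r", "scored_loci"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")

    kwargs = {k: data[k] for k in _SIMPLE_KEYS if k in data}
    map_keys = {"loci", "interval_r", "scored_loci"} & set(data)
    if map_keys:
        def _split(v, cast):
            if isinstance(v, str):
                v = [x.strip() for x in v.split(",") if x.strip()]
            return tuple(cast(x) for x in v)

        mm_kwargs = {}
        if "loci" in data:
            mm_kwargs["loci"] = _split(data["loci"], str)
        if "interval_r" in data:
            mm_kwargs["interval_r"] = _split(data["interval_r"], float)
        if "scored_loci" in data:
            mm_kwargs["scored_loci"] = _split(data["scored_loci"], str)
        kwargs["marker_map"] = MarkerMap(**mm_kwargs)
    return SimConfig(**kwargs).validate()


def write_sim_config(cfg: SimConfig, path) -> None:
    lines = [
        f"p_arm_loss: {cfg.p_arm_loss}",
        f"p_mii_loss: {cfg.p_mii_loss}",
        f"backup_enabled: {str(cfg.backup_enabled).lower()}",
        f"backup_efficiency: {cfg.backup_efficiency}",
        f"obligate_chiasma: {str(cfg.obligate_chiasma).lower()}",
        f"n_oocytes: {cfg.n_oocytes}",
        f"seed: {cfg.seed}",
        f"loci: {', '.join(cfg.marker_map.loci)}",
        f"interval_r: {', '.join(str(r) for r in cfg.marker_map.interval_r)}",
        f"scored_loci: {', '.join(cfg.marker_map.scored_loci)}",
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_ova_table(ova: OvaTable, path) -> None:
    """Export simulated ova for inspection (one row per ovum)."""
    ova.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a command's outputs byte-identically."""

    command: str
    seed: int | None
    inputs: dict
    outputs: dict
    config: dict | None = None
    package_version: str = __version__
    timestamp: str = ""

    def write(self, path, fill_timestamp: bool = True) -> None:
        data = dataclasses.asdict(self)
        if fill_timestamp and not data["timestamp"]:
            data["timestamp"] = _dt.datetime.now(_dt.timezone.utc).isoformat()
        Path(path).write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
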