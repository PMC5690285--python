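"""Reading and writing PSM tables, configurations and result files.

The canonical table dialect is tab-delimited UTF-8 text with ``#`` comment
lines; comma-delimited files are accepted on read. Results are written as a
per-state TSV of headline numbers plus a JSON audit file carrying every
intermediate; reading the JSON back reproduces the result object exactly.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .silac import STATES, NOT_APPLICABLE, SilacStoichiometryResult
from .tmt import TMTResult


class SchemaError(ValueError):
    """A PSM table violates the expected column layout or value types."""


#: Required / optional columns per experiment kind.
SILAC_REQUIRED = ("sequence", "protein", "p62_state", "quan_result_id",
                  "confidence", "unique")
SILAC_OPTIONAL = ("intensity_h", "intensity_l", "ratio_hl", "sample")
TMT_REQUIRED = ("sequence", "p62_state", "intensity_ch1", "intensity_ch2",
                "quan_result_id")

_STATE_ALIASES = {
    "unmodified": "unmodified", "unmod": "unmodified", "none": "unmodified",
    "mono": "mono", "monohydroxylated": "mono", "oxidation": "mono",
    "di": "di", "dihydroxylated": "di", "dioxidation": "di",
    "na": NOT_APPLICABLE, "not-applicable": NOT_APPLICABLE, "": NOT_APPLICABLE,
}

_TRUTHY = {"1", "true", "yes", "high", "y", "t"}
_FALSY = {"0", "false", "no", "low", "n", "f", ""}


def parse_modification_state(modifications: str, contains_p62: bool) -> str:
    """Map a search-engine modification string to a P62 state label.

    ``"dioxidation@P62"`` -> ``"di"``, ``"oxidation@P62"`` -> ``"mono"``; a
    site-covering peptide with neither is ``"unmodified"``; a peptide not
    covering the site is ``"na"`` regardless of its modifications.
    """
    if not contains_p62:
        return NOT_APPLICABLE
    mods = (modifications or "").lower()
    if re.search(r"dioxidation\s*@?\s*p", mods):
        return "di"
    if re.search(r"(?<!di)oxidation\s*@?\s*p", mods):
        return "mono"
    return "unmodified"


def _coerce_bool(series: pd.Series, column: str) -> pd.Series:
    def one(v, idx):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s in _TRUTHY:
            return True
        if s in _FALSY:
            return False
        raise SchemaError(f"row {idx}: cannot parse {column}={v!r} as boolean")
    return pd.Series([one(v, i) for i, v in series.items()], index=series.index)


def _coerce_numeric(series: pd.Series, column: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna() & (series.astype(str).str.strip() != "")
    if bad.any():
        idx = int(bad.idxmax())
        raise SchemaError(
            f"row {idx}: cannot parse {column}={series.loc[idx]!r} as a number"
        )
    return out


def _sniff_delimiter(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    return "\t"


def read_psm_table(
    path, kind: str = "silac", column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read and validate a delimited PSM table.

    ``column_map`` renames source columns to canonical names (e.g.
    ``{"Annotated Sequence": "sequence"}``) before validation, so exports
    with vendor-specific headers can be ingested without editing the file.
    If ``p62_state`` is absent but ``modifications`` and ``contains_p62``
    are present, the state is derived from the modification string.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: no such file")
    df = pd.read_csv(path, sep=_sniff_delimiter(path), comment="#", dtype=str)
    # row numbers in error messages refer to the data rows, 1-based
    df.index = pd.RangeIndex(1, len(df) + 1)
    if column_map:
        df = df.rename(columns=dict(column_map))
    df.columns = [c.strip().lower().replace(" ", "_") for c in df.columns]

    if "p62_state" not in df.columns and {"modifications", "contains_p62"} <= set(df.columns):
        covers = _coerce_bool(df["contains_p62"], "contains_p62")
        df["p62_state"] = [
            parse_modification_state(m, c)
            for m, c in zip(df["modifications"].fillna(""), covers)
        ]

    required = SILAC_REQUIRED if kind == "silac" else TMT_REQUIRED
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )

    def norm_state(v, idx):
        key = str(v).strip().lower() if v is not None and not pd.isna(v) else ""
        if key not in _STATE_ALIASES:
            raise SchemaError(f"row {idx}: unknown p62_state {v!r}")
        return _STATE_ALIASES[key]

    df["p62_state"] = [norm_state(v, i) for i, v in df["p62_state"].items()]

    if kind == "silac":
        df["confidence"] = _coerce_bool(df["confidence"], "confidence")
        df["unique"] = _coerce_bool(df["unique"], "unique")
        for col in ("intensity_h", "intensity_l", "ratio_hl"):
            if col in df.columns:
                df[col] = _coerce_numeric(df[col], col)
        if not {"intensity_h", "intensity_l", "ratio_hl"} & set(df.columns):
            raise SchemaError(
                f"{path}: need intensity_h/intensity_l or ratio_hl for quantification"
            )
    else:
        for col in ("intensity_ch1", "intensity_ch2"):
            df[col] = _coerce_numeric(df[col], col)
    return df


def write_psm_table(df: pd.DataFrame, path, header: Mapping | None = None) -> None:
    """Write a PSM table as TSV with an optional ``# key: value`` header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (header or {}).items():
            if isinstance(value, (dict, list, tuple)):
                value = json.dumps(value)
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table_header(path) -> dict:
    """Parse the ``# key: value`` comment header of a table written by us."""
    out = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            value = value.strip()
            try:
                out[key.strip()] = json.loads(value)
            except json.JSONDecodeError:
                out[key.strip()] = value
    return out


def load_config(path) -> dict:
    """Load a YAML (or JSON) key-value run configuration."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: no such file")
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a key-value mapping")
    return cfg


def _sig6(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    return f"{x:.6g}"


def write_results(result, out_dir, config_echo: Mapping | None = None,
                  seed: int | None = None) -> tuple[Path, Path]:
    """Write a result object as ``results.tsv`` + ``audit.json``.

    The TSV carries the headline per-state numbers at 6 significant digits;
    the JSON audit stores every intermediate at full precision plus the
    software version and the echoed configuration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / "results.tsv"
    json_path = out_dir / "audit.json"

    if isinstance(result, SilacStoichiometryResult):
        kind = "silac"
        lines = ["state\tn_psms\tpercent_heavy\tpercent_light\tp_value"]
        for state in STATES:
            r = result.states.get(state)
            if r is None or r.absent:
                lines.append(f"{state}\t0\tNA\tNA\tNA")
            else:
                lines.append(
                    f"{state}\t{r.n_psms}\t{_sig6(r.percent_heavy)}"
                    f"\t{_sig6(r.percent_light)}\t{_sig6(r.p_value)}"
                )
    elif isinstance(result, TMTResult):
        kind = "tmt"
        lines = ["state\tn_psms\tfold_change\tfold_change_geometric\tp_value"]
        for state in STATES:
            r = result.states.get(state)
            if r is None or r.absent:
                lines.append(f"{state}\t0\tNA\tNA\tNA")
            else:
                lines.append(
                    f"{state}\t{r.n_psms}\t{_sig6(r.fold_change)}"
                    f"\t{_sig6(r.fold_change_geometric)}\t{_sig6(r.p_value)}"
                )
    else:
        raise TypeError(f"unsupported result type {type(result).__name__}")

    tsv_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    audit = {
        "kind": kind,
        "version": __version__,
        "seed": seed,
        "config": dict(config_echo or {}),
        "result": result.to_dict(),
    }
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(audit, fh, indent=2)
    return tsv_path, json_path


def read_results_json(path):
    """Rebuild a result object from an ``audit.json`` file."""
    with open(path, encoding="utf-8") as fh:
        audit = json.load(fh)
    if audit["kind"] == "silac":
        return SilacStoichiometryResult.from_dict(audit["result"])
    if audit["kind"] == "tmt":
        return TMTResult.from_dict(audit["result"])
    raise SchemaError(f"{path}: unknown result kind {audit.get('kind')!r}")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a plain multi-record FASTA; returns (description, sequence) pairs."""
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: no such file")
    return [(rec.description, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
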