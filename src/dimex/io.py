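"""Readers and writers for the pipeline's plain-text formats.

Matrices travel as TSV with a feature-id first column; alternative-splicing
event catalogs use the SUPPA ioe dialect (tab-separated with comma-joined
transcript lists); gene sets use GMT (name, description, then members).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

IOE_COLUMNS = ["seqname", "gene_id", "event_id",
               "inclusion_transcripts", "total_transcripts"]


def read_matrix(path: str | Path, index_name: str = "feature_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = index_name
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_truth(path: str | Path) -> pd.DataFrame:
    """Read a ground-truth table; 'null' is an effect class, not missing data."""
    return pd.read_csv(path, sep="\t", index_col=0,
                       keep_default_na=False, na_values=[""])


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_ioe(path: str | Path) -> pd.DataFrame:
    """Read a SUPPA-style ioe event catalog.

    Expects a header line; alternative_transcripts/total_transcripts column
    names from SUPPA proper are accepted as synonyms.  The event type is
    parsed from the event id (``<event>;<TYPE>`` or SUPPA's
    ``gene;TYPE:coords``) when present.
    """
    df = pd.read_csv(path, sep="\t")
    rename = {"alternative_transcripts": "inclusion_transcripts",
              "seqname": "seqname", "gene_id": "gene_id",
              "event_id": "event_id", "total_transcripts": "total_transcripts"}
    df = df.rename(columns=rename)
    missing = [c for c in IOE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ioe file {path} lacks columns {missing}")
    if "event_type" not in df.columns:
        df["event_type"] = [
            _event_type_from_id(e) for e in df["event_id"]]
    return df.set_index("event_id")


def _event_type_from_id(event_id: str) -> str:
    known = {"SE", "A3", "A5", "AF", "AL", "MX", "RI"}
    for token in str(event_id).replace(":", ";").split(";"):
        if token in known:
            return token
    return "NA"


def write_ioe(catalog: pd.DataFrame, path: str | Path) -> None:
    out = catalog.reset_index()[IOE_COLUMNS]
    out.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets; duplicate members within a set are dropped."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            seen: dict[str, None] = {}
            for g in parts[2:]:
                if g and g not in seen:
                    seen[g] = None
            sets[parts[0]] = list(seen)
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description] + list(members)) + "\n")
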