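"""Tabular interchange: TSV readers/writers for the pipeline's tables.

TSV is the universal tabular format here; every file carries a header row.
Coordinates in BED output are 0-based half-open (see reference module);
human-readable reports label 1-based positions explicitly.
"""

from __future__ import annotations

import pandas as pd

from .errors import InputError

__all__ = [
    "read_tsv",
    "write_tsv",
    "parse_membership",
    "consortium_sizes",
    "read_presence",
    "write_presence",
]


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def parse_membership(path_or_df) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Parse a consortium membership table.

    Expects columns ``strain_id`` and ``consortium`` and optionally ``role``
    (donor/recipient). Returns ``(consortia, roles)``: consortium name ->
    strain set, and consortium name -> role (empty dict when absent).
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else read_tsv(path_or_df)
    for col in ("strain_id", "consortium"):
        if col not in df.columns:
            raise InputError(f"membership table lacks column {col!r}")
    dup = df.duplicated(subset=["strain_id", "consortium"])
    if dup.any():
        raise InputError("duplicate strain/consortium rows in membership table")
    consortia = {name: set(sub["strain_id"]) for name, sub in df.groupby("consortium")}
    roles: dict[str, str] = {}
    if "role" in df.columns:
        for name, sub in df.groupby("consortium"):
            r = set(sub["role"])
            if len(r) != 1:
                raise InputError(f"consortium {name!r} has conflicting roles {sorted(r)!r}")
            roles[name] = r.pop()
    return consortia, roles


def consortium_sizes(consortia: dict[str, set[str]], roles: dict[str, str] | None = None,
                     role: str | None = None) -> pd.Series:
    """Strain counts per consortium, optionally restricted to one role."""
    names = list(consortia)
    if role is not None:
        if not roles:
            raise InputError("role filter requested but membership table has no roles")
        names = [n for n in names if roles.get(n) == role]
    return pd.Series({n: len(consortia[n]) for n in names}, name="n_strains").sort_index()


def read_presence(path) -> pd.DataFrame:
    """Load a presence matrix TSV with mouse_id/timepoint index columns."""
    df = read_tsv(path)
    for col in ("mouse_id", "timepoint"):
        if col not in df.columns:
            raise InputError(f"presence table lacks column {col!r}")
    df = df.set_index(["mouse_id", "timepoint"])
    return df.astype(bool)


def write_presence(presence: pd.DataFrame, path) -> None:
    presence.astype(int).reset_index().to_csv(path, sep="\t", index=False)
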