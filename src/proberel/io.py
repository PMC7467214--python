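"""Tabular input/output for the reliability pipeline.

All interchange is delimited text (TSV by default).  The formats are:

* **beta matrix** — column 1 ``probe_id``, remaining columns sample ids,
  values in [0, 1] or ``NA``.
* **probe sets** — GMT-style (set name, description, tab-separated probe
  ids) or plain one-id-per-line.
* **study hit lists** — columns ``study_id, probe_id, direction`` where
  direction is ``up``/``down`` (``+``/``-`` accepted as synonyms).
* **external per-probe statistics** — columns ``probe_id, value``.

Probe identifiers are opaque strings; the ``cgXXXXXXXX`` convention of
Illumina manifests is accepted but not enforced, so synthetic ids work
everywhere.  Missing β values are encoded as ``NA`` and preserved on
round-trip; per-probe analyses downstream use complete pairs only.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "BetaMatrix",
    "PairedBetaMatrix",
    "ProbeSet",
    "StudyHitList",
    "read_beta_matrix",
    "write_beta_matrix",
    "pair_matrices",
    "read_probe_set",
    "read_gmt",
    "write_gmt",
    "read_study_hits",
    "write_study_hits",
    "read_external_stat",
    "write_external_stat",
]

NA_TOKEN = "NA"

#: accepted spellings for direction of effect in study hit lists
DIRECTION_SYNONYMS = {
    "up": "up",
    "down": "down",
    "+": "up",
    "-": "down",
}


class SchemaError(ValueError):
    """A file does not have the expected layout (columns, duplicates...)."""


class ValidationError(ValueError):
    """A file parses but carries invalid values (β outside [0, 1]...)."""


# ---------------------------------------------------------------------------
# β matrices
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class BetaMatrix:
    """Probes × samples matrix of methylation β values.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with sample ids as columns.  Entries
        are β in [0, 1] or NaN for missing.
    platform_label
        Free-text label for the measurement platform (e.g. ``"450K"``).
    """

    values: pd.DataFrame
    platform_label: str = ""

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate probe ids: {dups[:5]}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dups[:5]}")
        vals = self.values.to_numpy(dtype=float)
        bad = (vals < 0.0) | (vals > 1.0)
        if np.any(bad):
            p, s = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {vals[p, s]!r} outside [0, 1] at probe "
                f"{idx[p]!r}, sample {cols[s]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclasses.dataclass
class PairedBetaMatrix:
    """Two β matrices aligned on a common probe set and paired samples.

    After pairing both matrices share an identical ordered probe index,
    and column ``j`` of ``second`` is the repeat measurement of column
    ``j`` of ``first``.  ``dropped_probes``/``dropped_samples`` record
    what the intersection discarded from either input.
    """

    first: BetaMatrix
    second: BetaMatrix
    sample_pairs: list[tuple[str, str]]
    dropped_probes: dict = dataclasses.field(default_factory=dict)
    dropped_samples: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.first.values.index) != list(self.second.values.index):
            raise SchemaError("paired matrices must share an ordered probe index")
        if self.first.shape[1] != self.second.shape[1]:
            raise SchemaError("paired matrices must have equal sample counts")

    @property
    def probe_ids(self) -> list[str]:
        return self.first.probe_ids

    @property
    def n_pairs(self) -> int:
        return self.first.shape[1]


def read_beta_matrix(
    path: str | Path, delimiter: str = "\t", platform_label: str | None = None
) -> BetaMatrix:
    """Read a β matrix from delimited text.

    The first column must be named ``probe_id``; the header row carries
    sample ids.  ``NA`` cells become NaN.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=delimiter,
        index_col=0,
        na_values=[NA_TOKEN],
        keep_default_na=False,
        float_precision="round_trip",
    )
    if df.index.name != "probe_id":
        raise SchemaError(
            f"{path}: first column must be named 'probe_id', got {df.index.name!r}"
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric beta value ({exc})") from exc
    label = platform_label if platform_label is not None else path.stem
    return BetaMatrix(df, platform_label=label)


def write_beta_matrix(matrix: BetaMatrix, path: str | Path, delimiter: str = "\t") -> None:
    df = matrix.values.copy()
    df.index.name = "probe_id"
    # 17 significant digits keep the round-trip bitwise exact for float64
    df.to_csv(path, sep=delimiter, na_rep=NA_TOKEN, float_format=lambda v: format(v, ".17g"))


def pair_matrices(
    a: BetaMatrix,
    b: BetaMatrix,
    sample_map: Mapping[str, str] | None = None,
) -> PairedBetaMatrix:
    """Align two β matrices measured on the same DNA into a paired object.

    Parameters
    ----------
    a, b
        The two measurement occasions (e.g. 450K and EPIC runs).
    sample_map
        Maps a sample id in ``a`` to its repeat in ``b``.  Defaults to the
        identity map over shared sample ids.  Must be one-to-one.

    Returns
    -------
    PairedBetaMatrix
        Restricted to the probe intersection and mapped samples, with a
        report of dropped probes and samples.
    """
    if sample_map is None:
        shared = [s for s in a.sample_ids if s in set(b.sample_ids)]
        sample_map = {s: s for s in shared}
    targets = list(sample_map.values())
    if len(set(targets)) != len(targets):
        raise SchemaError("sample_map is many-to-one; pairing must be one-to-one")

    b_samples = set(b.sample_ids)
    pairs = [
        (sa, sb)
        for sa, sb in sample_map.items()
        if sa in set(a.sample_ids) and sb in b_samples
    ]
    # keep the column order of `a`
    order = {s: i for i, s in enumerate(a.sample_ids)}
    pairs.sort(key=lambda p: order[p[0]])
    if not pairs:
        raise SchemaError("no paired samples after applying sample_map")

    probes_a, probes_b = set(a.probe_ids), set(b.probe_ids)
    shared_probes = [p for p in a.probe_ids if p in probes_b]
    if not shared_probes:
        raise SchemaError("probe intersection of the two matrices is empty")

    first = BetaMatrix(
        a.values.loc[shared_probes, [p[0] for p in pairs]], a.platform_label
    )
    second_df = b.values.loc[shared_probes, [p[1] for p in pairs]]
    second = BetaMatrix(second_df, b.platform_label)
    return PairedBetaMatrix(
        first,
        second,
        sample_pairs=pairs,
        dropped_probes={
            "first_only": sorted(probes_a - probes_b),
            "second_only": sorted(probes_b - probes_a),
        },
        dropped_samples={
            "first_only": [s for s in a.sample_ids if s not in {p[0] for p in pairs}],
            "second_only": [s for s in b.sample_ids if s not in {p[1] for p in pairs}],
        },
    )


# ---------------------------------------------------------------------------
# probe sets
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ProbeSet:
    """A named set of probe ids (e.g. clock CpGs, mQTL probes)."""

    name: str
    probe_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise ValidationError(f"probe set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.probe_ids)


def read_probe_set(path: str | Path, name: str | None = None) -> ProbeSet:
    """Read a plain one-id-per-line probe set file."""
    path = Path(path)
    ids = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    if len(set(ids)) != len(ids):
        raise SchemaError(f"{path}: duplicate probe ids in probe set")
    return ProbeSet(name or path.stem, frozenset(ids))


def read_gmt(path: str | Path) -> list[ProbeSet]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>id...``."""
    sets = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise SchemaError(f"{path}:{ln}: GMT line needs name, description, >=1 id")
        name, _desc, *ids = fields
        ids = [i for i in ids if i]
        if len(set(ids)) != len(ids):
            raise SchemaError(f"{path}:{ln}: duplicate ids in set {name!r}")
        sets.append(ProbeSet(name, frozenset(ids)))
    return sets


def write_gmt(sets: Sequence[ProbeSet], path: str | Path, description: str = ".") -> None:
    with open(path, "w") as fh:
        for ps in sets:
            fh.write("\t".join([ps.name, description, *sorted(ps.probe_ids)]) + "\n")


# ---------------------------------------------------------------------------
# study hit lists
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class StudyHitList:
    """Significant probes from one EWAS with direction of effect."""

    study_id: str
    entries: list[tuple[str, str]]  # (probe_id, "up"|"down")

    def __post_init__(self) -> None:
        probes = [p for p, _ in self.entries]
        if len(set(probes)) != len(probes):
            raise SchemaError(f"study {self.study_id!r}: duplicate probe entries")
        for p, d in self.entries:
            if d not in ("up", "down"):
                raise ValidationError(
                    f"study {self.study_id!r}, probe {p!r}: direction {d!r} "
                    f"not in {sorted(set(DIRECTION_SYNONYMS.values()))}"
                )

    @property
    def probe_ids(self) -> set[str]:
        return {p for p, _ in self.entries}


def read_study_hits(path: str | Path, delimiter: str = "\t") -> list[StudyHitList]:
    """Read hit lists for one or more studies from a long-format table."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    required = {"study_id", "probe_id", "direction"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: columns must include {sorted(required)}")
    out = []
    for study_id, grp in df.groupby("study_id", sort=True):
        entries = []
        for probe, direction in zip(grp["probe_id"], grp["direction"]):
            token = str(direction).strip().lower()
            if token not in DIRECTION_SYNONYMS:
                raise ValidationError(
                    f"{path}: study {study_id!r}, probe {probe!r}: "
                    f"unrecognized direction {direction!r}"
                )
            entries.append((str(probe), DIRECTION_SYNONYMS[token]))
        out.append(StudyHitList(str(study_id), entries))
    return out


def write_study_hits(hits: Sequence[StudyHitList], path: str | Path) -> None:
    rows = [
        {"study_id": h.study_id, "probe_id": p, "direction": d}
        for h in hits
        for p, d in h.entries
    ]
    pd.DataFrame(rows, columns=["study_id", "probe_id", "direction"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# external per-probe statistics
# ---------------------------------------------------------------------------


def read_external_stat(path: str | Path, delimiter: str = "\t") -> pd.Series:
    """Read a per-probe external statistic (``probe_id, value``) as a Series."""
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    if df.shape[1] != 2 or df.columns[0] != "probe_id":
        raise SchemaError(f"{path}: expected exactly columns ('probe_id', <value>)")
    if df["probe_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate probe ids")
    s = pd.Series(
        df.iloc[:, 1].astype(float).to_numpy(),
        index=df["probe_id"].astype(str),
        name=df.columns[1],
    )
    return s


def write_external_stat(stat: pd.Series, path: str | Path) -> None:
    df = stat.rename_axis("probe_id").reset_index()
    df.to_csv(path, sep="\t", index=False, float_format=lambda v: format(v, ".17g"))
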