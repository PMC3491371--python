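"""Domain containers and plain-text I/O for expression analysis.

Everything in this package operates on a features x samples expression
matrix plus a per-sample phenotype table.  The phenotype table carries the
*anchor* flag — the labeled minority population (stem cells in the original
application) whose localized expression the sliding-window statistic
rewards — together with free-form group labels and optional ordered grade
and stage annotations used for downstream evaluation.

File formats are deliberately plain: TSV/CSV with a sample-id header row
and a feature-id first column for matrices, a named-column TSV for
phenotypes, standard GMT for gene-set collections and a two-column TSV for
ortholog maps.  Missing values are not supported; inputs must be complete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_DIALECT_SEP = {"tsv": "\t", "csv": ","}

__all__ = [
    "ExpressionMatrix",
    "PhenotypeTable",
    "GeneSetCollection",
    "OrthologMap",
    "ProbeGeneMap",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_phenotypes",
    "write_phenotypes",
    "read_gene_sets",
    "read_ortholog_map",
    "read_signature",
    "write_signature",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


class ExpressionMatrix:
    """A features x samples matrix of finite numeric values.

    Values are dimensionless intensities, or fractional ranks in (0, 1]
    after rank normalization.  Feature and sample identifiers are unique.
    """

    def __init__(
        self,
        values: np.ndarray | Sequence[Sequence[float]],
        feature_ids: Sequence[str],
        sample_ids: Sequence[str],
    ):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if values.shape != (len(feature_ids), len(sample_ids)):
            raise ValueError(
                f"shape {values.shape} does not match {len(feature_ids)} "
                f"features x {len(sample_ids)} samples"
            )
        _check_unique(list(feature_ids), "feature")
        _check_unique(list(sample_ids), "sample")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at feature {feature_ids[bad[0]]!r}, "
                f"sample {sample_ids[bad[1]]!r}"
            )
        self.data = pd.DataFrame(
            values, index=list(feature_ids), columns=list(sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix.from_frame(self.data.loc[:, list(sample_ids)])

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix.from_frame(self.data.loc[list(feature_ids)])

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ExpressionMatrix({self.shape[0]} features x {self.shape[1]} samples)"


class PhenotypeTable:
    """Per-sample labels: anchor flag, group, optional ordered grade/stage."""

    MANDATORY = ("sample_id", "is_anchor", "group")
    OPTIONAL = ("grade", "stage")

    def __init__(self, frame: pd.DataFrame):
        for col in ("is_anchor", "group"):
            if col not in frame.columns:
                raise ValueError(f"phenotype table missing mandatory column {col!r}")
        _check_unique(list(frame.index), "sample")
        out = frame.copy()
        out["is_anchor"] = out["is_anchor"].astype(bool)
        out["group"] = out["group"].astype(str)
        self.data = out

    @classmethod
    def from_records(
        cls,
        sample_ids: Sequence[str],
        is_anchor: Sequence[bool],
        group: Sequence[str],
        grade: Sequence | None = None,
        stage: Sequence | None = None,
    ) -> "PhenotypeTable":
        frame = pd.DataFrame(
            {"is_anchor": list(is_anchor), "group": list(group)},
            index=list(sample_ids),
        )
        if grade is not None:
            frame["grade"] = list(grade)
        if stage is not None:
            frame["stage"] = list(stage)
        return cls(frame)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def is_anchor(self) -> pd.Series:
        return self.data["is_anchor"]

    @property
    def group(self) -> pd.Series:
        return self.data["group"]

    def column(self, name: str) -> pd.Series | None:
        return self.data[name] if name in self.data.columns else None

    def anchor_ids(self) -> list[str]:
        return list(self.data.index[self.data["is_anchor"]])

    def anchor_mask(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Boolean anchor mask aligned to ``sample_ids``; validates coverage."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValueError(f"samples absent from phenotype table: {missing[:5]}")
        return self.data.loc[list(sample_ids), "is_anchor"].to_numpy(dtype=bool)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (GMT-shaped)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class OrthologMap:
    """One-to-one source -> target feature-id map.

    Entries whose source *or* target appears more than once in the raw
    input are dropped at load time (uniqueness enforced in both
    directions), so the retained map is a bijection on its domain.
    """

    pairs: dict[str, str] = field(default_factory=dict)

    @staticmethod
    def filter_unique(raw_pairs: Iterable[tuple[str, str]]) -> "OrthologMap":
        raw = list(raw_pairs)
        src_counts: dict[str, int] = {}
        tgt_counts: dict[str, int] = {}
        for s, t in raw:
            src_counts[s] = src_counts.get(s, 0) + 1
            tgt_counts[t] = tgt_counts.get(t, 0) + 1
        kept = {s: t for s, t in raw if src_counts[s] == 1 and tgt_counts[t] == 1}
        dropped = len(raw) - len(kept)
        if dropped:
            log.info("ortholog map: dropped %d non-unique entries of %d", dropped, len(raw))
        return OrthologMap(kept)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ProbeGeneMap:
    """Many-to-one probe-set -> gene map; each probe maps to one gene."""

    pairs: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a features x samples matrix from TSV/CSV.

    The first row is the sample header; the first column holds feature ids.
    Duplicate ids and non-numeric cells raise ``ValueError`` naming the
    offender.
    """
    sep = _DIALECT_SEP[dialect]
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    sample_ids = header[1:]
    _check_unique(sample_ids, "sample")
    frame = pd.read_csv(path, sep=sep, index_col=0, header=0)
    _check_unique(list(frame.index.astype(str)), "feature")
    # locate any non-numeric cell precisely before the cast can hide it
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at feature {frame.index[r]!r}, sample "
            f"{frame.columns[c]!r}: {frame.iat[r, c]!r}"
        )
    return ExpressionMatrix(
        numeric.to_numpy(dtype=float), [str(i) for i in frame.index], sample_ids
    )


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    dialect: str = "tsv",
    float_format: str = "%.10g",
) -> None:
    matrix.data.to_csv(
        path, sep=_DIALECT_SEP[dialect], float_format=float_format,
        index_label="feature_id",
    )


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read the per-sample annotation TSV (sample_id, is_anchor, group, ...)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in PhenotypeTable.MANDATORY:
        if col not in frame.columns:
            raise ValueError(f"phenotype file missing mandatory column {col!r}")
    extra = [
        c for c in frame.columns
        if c not in PhenotypeTable.MANDATORY + PhenotypeTable.OPTIONAL
    ]
    if extra:
        log.info("phenotype file: ignoring unknown columns %s", extra)
    _check_unique(list(frame["sample_id"]), "sample")
    truthy = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}
    try:
        anchors = [truthy[str(v).strip().lower()] for v in frame["is_anchor"]]
    except KeyError as exc:
        raise ValueError(f"unparseable is_anchor value: {exc.args[0]!r}") from None
    out = pd.DataFrame(
        {"is_anchor": anchors, "group": frame["group"].astype(str)},
        index=list(frame["sample_id"]),
    )
    for col in PhenotypeTable.OPTIONAL:
        if col in frame.columns:
            out[col] = list(frame[col])
    return PhenotypeTable(out)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.data.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then members."""
    coll = GeneSetCollection()
    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {lineno}: needs name, "
                                 f"description and at least one member")
            name, desc, *members = fields
            # keep members unique within the set, preserving order
            seen: set[str] = set()
            uniq = [m for m in members if m and not (m in seen or seen.add(m))]
            coll.sets[name] = uniq
            coll.descriptions[name] = desc
    if n_lines == 0:
        raise ValueError(f"empty gene-set file: {path}")
    return coll


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column source/target TSV, dropping non-unique entries."""
    raw: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"malformed ortholog line {lineno}: expected "
                                 f"2 columns, got {len(fields)}")
            raw.append((fields[0], fields[1]))
    if not raw:
        raise ValueError(f"empty ortholog file: {path}")
    return OrthologMap.filter_unique(raw)


def read_probe_gene_map(path: str | Path) -> ProbeGeneMap:
    """Read a two-column probe/gene TSV (many probes may share a gene)."""
    pairs: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"malformed probe-map line {lineno}")
            probe, gene = fields
            if probe in pairs and pairs[probe] != gene:
                raise ValueError(f"probe {probe!r} maps to multiple genes")
            pairs[probe] = gene
    if not pairs:
        raise ValueError(f"empty probe map: {path}")
    return ProbeGeneMap(pairs)


def read_signature(path: str | Path) -> list[str]:
    """Read a signature file: one gene id per line."""
    with open(path, encoding="utf-8") as fh:
        genes = [ln.strip() for ln in fh if ln.strip()]
    if not genes:
        raise ValueError(f"empty signature file: {path}")
    _check_unique(genes, "signature gene")
    return genes


def write_signature(gene_ids: Sequence[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in gene_ids:
            fh.write(f"{g}\n")
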