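"""Reading and writing of count matrices, gene lengths, gene lists and reports.

All external artifacts are plain text: tab-separated matrices (genes as
rows, samples as columns), two-column length tables or GTF annotation,
one-ID-per-line gene lists, and tsv/json reports.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "GeneList",
    "FormatError",
    "read_counts",
    "read_group_map",
    "read_gene_lengths",
    "read_gene_list",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_counts",
    "write_report",
    "read_reference_set",
    "read_stability_report",
    "read_size_factors",
    "common_reference_genes",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected format or an invariant."""


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame with gene IDs as index and sample IDs as columns.
    groups
        Optional mapping from sample ID to group label. When present it
        must cover every sample.
    """

    counts: pd.DataFrame
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene ID {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample ID {dup!r}")
        if len(idx) == 0:
            raise FormatError("no genes")
        if len(cols) == 0:
            raise FormatError("no samples")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError("counts must be numeric")
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            bad = np.argwhere((vals < 0) | (vals != np.round(vals)))[0]
            raise FormatError(
                f"non-integer or negative count at gene {idx[bad[0]]!r}, "
                f"sample {cols[bad[1]]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        if self.groups is not None:
            missing = [s for s in cols if s not in self.groups]
            if missing:
                raise FormatError(f"sample {missing[0]!r} has no group label")
            unknown = [s for s in self.groups if s not in cols]
            if unknown:
                raise FormatError(f"group map references unknown sample {unknown[0]!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class GeneList:
    """A named, ordered, duplicate-free list of gene IDs."""

    name: str
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise FormatError(f"gene list {self.name!r} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            for g in self.gene_ids:
                if g in seen:
                    raise FormatError(f"duplicate gene ID {g!r} in list {self.name!r}")
                seen.add(g)

    def __len__(self) -> int:
        return len(self.gene_ids)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples tsv matrix (header = sample IDs, col 0 = gene IDs)."""
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.index.name = None
    if df.shape[0] == 0:
        raise FormatError("no genes")
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, float_format: str | None = None) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format=float_format)


def read_counts(path: str | Path, group_map: str | Path | None = None) -> CountMatrix:
    """Read a count matrix, optionally with a sample-to-group map.

    The counts file is tab-separated with a header row of sample IDs and
    gene IDs in the first column (a leading ``gene_id`` header cell is
    accepted). The group map is two tab-separated columns
    ``sample_id<TAB>group`` with no header requirement.
    """
    df = read_matrix_tsv(path)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene ID {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            gene = df.index[coerced.isna()][0]
            raise FormatError(
                f"non-integer or negative count at gene {gene!r}, sample {col!r}"
            )
        df[col] = coerced
    groups = read_group_map(group_map) if group_map is not None else None
    return CountMatrix(df, groups=dict(groups) if groups is not None else None)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    write_matrix_tsv(cm.counts, path)


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample-to-group table (a ``sample_id`` header row is skipped)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"malformed group-map line: {line!r}")
        if parts[0] in ("sample_id", "sample") and not out:
            continue
        if parts[0] in out:
            raise FormatError(f"duplicate sample {parts[0]!r} in group map")
        out[parts[0]] = parts[1]
    if not out:
        raise FormatError("empty group map")
    return out


def _merged_interval_length(intervals: list[tuple[int, int]]) -> int:
    """Total bases covered by a union of 1-based inclusive intervals."""
    total = 0
    cur_start = cur_end = None
    for start, end in sorted(intervals):
        if cur_end is None:
            cur_start, cur_end = start, end
        elif start <= cur_end + 1:
            cur_end = max(cur_end, end)
        else:
            total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
    if cur_end is not None:
        total += cur_end - cur_start + 1
    return total


def _lengths_from_gtf(path: str | Path) -> pd.Series:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    for feat in db.features_of_type("exon"):
        gene_ids = feat.attributes.get("gene_id")
        if not gene_ids:
            continue
        exons.setdefault(gene_ids[0], []).append((feat.start, feat.end))
    if not exons:
        raise FormatError("GTF contains no exon features with gene_id attributes")
    lengths = {g: _merged_interval_length(iv) for g, iv in exons.items()}
    return pd.Series(lengths, dtype=np.int64).sort_index()


def read_gene_lengths(path: str | Path, format: str = "tsv") -> pd.Series:
    """Read gene lengths from a two-column tsv or compute exonic-union lengths from a GTF.

    For GTF input the length of a gene is the number of bases covered by
    the union of all its exon intervals (1-based inclusive coordinates,
    overlaps merged, strand ignored).
    """
    if format == "gtf":
        return _lengths_from_gtf(path)
    if format != "tsv":
        raise ValueError(f"unknown length format {format!r}")
    lengths: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"malformed length line: {line!r}")
        if parts[0] in ("gene_id", "gene") and not lengths:
            continue
        try:
            length = int(parts[1])
        except ValueError as exc:
            raise FormatError(f"non-integer length for gene {parts[0]!r}") from exc
        if length <= 0:
            raise FormatError(f"non-positive length for gene {parts[0]!r}")
        lengths[parts[0]] = length
    if not lengths:
        raise FormatError("empty length table")
    return pd.Series(lengths, dtype=np.int64)


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Read a gene list, one ID per line; blank lines and ``#`` comments ignored."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    return GeneList(name=name or Path(path).stem, gene_ids=ids)


def common_reference_genes() -> GeneList:
    """The packaged set of 14 commonly used Arabidopsis reference genes.

    Actins, tubulins, polyubiquitins, APT1, EF1-alpha, eIF4A and NDUFA8 —
    the classical qPCR housekeeping panel used as the comparison baseline
    for custom-selected references.
    """
    text = (
        resources.files("refpick").joinpath("data/common_references_tair.txt").read_text()
    )
    ids = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return GeneList(name="common", gene_ids=ids)


# ---------------------------------------------------------------------------
# Reports


def _sig6(x: float) -> float:
    return float(f"{x:.6g}")


def write_report(report, path: str | Path, format: str = "tsv") -> None:
    """Write a ReferenceSet, StabilityReport or SizeFactorSet to tsv or json.

    Floating values are written with 6 significant digits; the written
    file round-trips through the matching ``read_*`` function.
    """
    # local imports avoid a circular dependency at module load
    from .refnorm import SizeFactorSet
    from .selection import ReferenceSet
    from .stability import StabilityReport

    path = Path(path)
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown report format {format!r}")
    if isinstance(report, ReferenceSet):
        _write_reference_set(report, path, format)
    elif isinstance(report, StabilityReport):
        _write_stability_report(report, path, format)
    elif isinstance(report, SizeFactorSet):
        _write_size_factors(report, path, format)
    else:
        raise TypeError(f"cannot serialize report of type {type(report).__name__}")


def _write_reference_set(report, path: Path, format: str) -> None:
    rows = [
        {
            "gene_id": g,
            "mean_tpm": _sig6(m),
            "cv_percent": _sig6(c),
        }
        for g, m, c in zip(report.gene_ids, report.mean_tpm, report.cv_percent)
    ]
    if format == "json":
        path.write_text(json.dumps({"params": report.params, "genes": rows}, indent=1))
        return
    with open(path, "w") as fh:
        for key, val in report.params.items():
            fh.write(f"# {key}={val}\n")
        fh.write("gene_id\tmean_tpm\tcv_percent\n")
        for r in rows:
            fh.write(f"{r['gene_id']}\t{r['mean_tpm']:.6g}\t{r['cv_percent']:.6g}\n")


def read_reference_set(path: str | Path, format: str = "tsv"):
    from .selection import ReferenceSet

    path = Path(path)
    if format == "json":
        obj = json.loads(path.read_text())
        genes = obj["genes"]
        return ReferenceSet(
            gene_ids=[r["gene_id"] for r in genes],
            mean_tpm=[r["mean_tpm"] for r in genes],
            cv_percent=[r["cv_percent"] for r in genes],
            params=obj["params"],
        )
    params: dict = {}
    rows = []
    lines = path.read_text().splitlines()
    for line in lines:
        if line.startswith("# ") and "=" in line:
            key, val = line[2:].split("=", 1)
            params[key] = _parse_scalar(val)
        elif line and not line.startswith("gene_id"):
            g, m, c = line.split("\t")
            rows.append((g, float(m), float(c)))
    return ReferenceSet(
        gene_ids=[r[0] for r in rows],
        mean_tpm=[r[1] for r in rows],
        cv_percent=[r[2] for r in rows],
        params=params,
    )


def _parse_scalar(val: str):
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            continue
    if val in ("True", "False"):
        return val == "True"
    return val


_STAB_COLS = [
    "gene_id",
    "genorm_rank",
    "mean_tpm",
    "cv_percent",
    "intergroup_diff",
    "intragroup_sd",
    "stability",
    "genorm_m",
]


def _write_stability_report(report, path: Path, format: str) -> None:
    table = report.table
    if format == "json":
        obj = {
            "set_name": report.set_name,
            "table": [
                {k: (_sig6(v) if isinstance(v, float) else v) for k, v in rec.items()}
                for rec in table.reset_index().rename(columns={"index": "gene_id"}).to_dict("records")
            ],
            "pairwise_variation": [_sig6(v) for v in report.pairwise_variation],
            "summary": {k: _sig6(v) if isinstance(v, float) else v for k, v in report.summary.items()},
        }
        path.write_text(json.dumps(obj, indent=1, allow_nan=True))
        return
    with open(path, "w") as fh:
        fh.write(f"# set={report.set_name}\n")
        fh.write("\t".join(_STAB_COLS) + "\n")
        for gene, row in table.iterrows():
            cells = [gene]
            for col in _STAB_COLS[1:]:
                v = row[col]
                if col == "genorm_rank":
                    cells.append("NA" if pd.isna(v) else str(int(v)))
                else:
                    cells.append("NA" if pd.isna(v) else f"{v:.6g}")
            fh.write("\t".join(cells) + "\n")


def read_stability_report(path: str | Path, format: str = "tsv"):
    from .stability import StabilityReport

    path = Path(path)
    if format == "json":
        obj = json.loads(path.read_text())
        table = pd.DataFrame(obj["table"]).set_index("gene_id")
        return StabilityReport(
            set_name=obj["set_name"],
            table=table,
            pairwise_variation=list(obj["pairwise_variation"]),
            summary=obj["summary"],
        )
    lines = path.read_text().splitlines()
    set_name = "set"
    rows = []
    for line in lines:
        if line.startswith("# set="):
            set_name = line[len("# set=") :]
        elif line and not line.startswith("gene_id") and not line.startswith("#"):
            cells = line.split("\t")
            rec = {"gene_id": cells[0]}
            for col, cell in zip(_STAB_COLS[1:], cells[1:]):
                rec[col] = np.nan if cell == "NA" else float(cell)
            rows.append(rec)
    table = pd.DataFrame(rows).set_index("gene_id")
    return StabilityReport(set_name=set_name, table=table, pairwise_variation=[], summary={})


def _write_size_factors(report, path: Path, format: str) -> None:
    if format == "json":
        obj = {
            "reference_set": report.reference_set,
            "n_usable_refs": report.n_usable_refs,
            "size_factors": {s: _sig6(v) for s, v in report.size_factors.items()},
        }
        path.write_text(json.dumps(obj, indent=1))
        return
    with open(path, "w") as fh:
        fh.write(f"# reference_set={report.reference_set}\n")
        fh.write(f"# n_usable_refs={report.n_usable_refs}\n")
        fh.write("sample_id\tsize_factor\n")
        for s, v in report.size_factors.items():
            fh.write(f"{s}\t{v:.6g}\n")


def read_size_factors(path: str | Path, format: str = "tsv"):
    from .refnorm import SizeFactorSet

    path = Path(path)
    if format == "json":
        obj = json.loads(path.read_text())
        return SizeFactorSet(
            size_factors=pd.Series(obj["size_factors"], dtype=float),
            reference_set=obj["reference_set"],
            n_usable_refs=int(obj["n_usable_refs"]),
        )
    ref_name = "refs"
    n_usable = 0
    factors: dict[str, float] = {}
    for line in path.read_text().splitlines():
        if line.startswith("# reference_set="):
            ref_name = line.split("=", 1)[1]
        elif line.startswith("# n_usable_refs="):
            n_usable = int(line.split("=", 1)[1])
        elif line and not line.startswith("sample_id") and not line.startswith("#"):
            s, v = line.split("\t")
            factors[s] = float(v)
    return SizeFactorSet(
        size_factors=pd.Series(factors, dtype=float),
        reference_set=ref_name,
        n_usable_refs=n_usable,
    )
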