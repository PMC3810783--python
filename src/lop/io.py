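"""Readers and writers for the plain-text interchange formats used by the pipeline.

Every format is line-oriented text (TSV, GMT, FASTA, JASPAR-style PFM blocks)
so that fixtures are diffable and round-trips are lossless.  All writers accept
an optional ``header`` mapping that is emitted as ``# key=value`` comment lines;
readers skip comment lines transparently.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """Malformed input; message names the file, line number and violated rule."""

    def __init__(self, path, line_no, rule):
        self.path, self.line_no, self.rule = str(path), line_no, rule
        super().__init__(f"{path}:{line_no}: {rule}")


SURVIVAL_COLUMNS = ["animal_id", "group", "time", "event"]
_OPTIONAL_SURVIVAL = ["genotype", "sex", "diet"]


def _header_lines(header: Mapping | None) -> str:
    if not header:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in header.items())


def _read_tsv(path, required: Sequence[str], dtypes: Mapping | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=dtypes)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(path, 0, f"unreadable TSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"missing required columns {missing}")
    return df


def write_survival(table: pd.DataFrame, path, header: Mapping | None = None) -> None:
    cols = SURVIVAL_COLUMNS + [c for c in _OPTIONAL_SURVIVAL if c in table.columns]
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        table[cols].to_csv(fh, sep="\t", index=False)


def read_survival(path) -> pd.DataFrame:
    df = _read_tsv(path, SURVIVAL_COLUMNS)
    if (df["time"] <= 0).any():
        bad = int(np.argmax(df["time"].to_numpy() <= 0)) + 2
        raise ParseError(path, bad, "lifespan must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ParseError(path, 0, "event flags must be 0 or 1")
    return df


def write_expression(matrix: pd.DataFrame, probe_to_gene: Mapping[str, str], path,
                     header: Mapping | None = None) -> None:
    """Matrix is probes x samples; the gene map is stored as a second column."""
    out = matrix.copy()
    out.insert(0, "gene", [probe_to_gene[p] for p in out.index])
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        out.to_csv(fh, sep="\t", index=True, index_label="probe_id")


def read_expression(path) -> tuple[pd.DataFrame, dict[str, str]]:
    df = _read_tsv(path, ["probe_id", "gene"]).set_index("probe_id")
    probe_to_gene = df["gene"].to_dict()
    matrix = df.drop(columns=["gene"])
    return matrix, probe_to_gene


def write_design(design: Mapping[str, str], path, header: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        fh.write("sample\tgroup\n")
        for s, g in design.items():
            fh.write(f"{s}\t{g}\n")


def read_design(path) -> dict[str, str]:
    df = _read_tsv(path, ["sample", "group"])
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))


def write_gmt(sets: Mapping[str, Iterable[str]], path, descriptions: Mapping[str, str] | None = None,
              header: Mapping | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        for name, genes in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(path, i, "GMT line needs >=3 tab-separated fields "
                                          "(name, description, genes...)")
            name = fields[0]
            if name in sets:
                raise ParseError(path, i, f"duplicate set name {name!r}")
            sets[name] = set(fields[2:])
    return sets


def write_fasta(seqs: Mapping[str, str], path, header: Mapping | None = None) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    """Case (soft-masking) is preserved exactly."""
    with open(path) as fh:
        text = "".join(line for line in fh if not line.startswith("#"))
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(_io.StringIO(text), "fasta")}


def write_pfms(pfms: Mapping[str, np.ndarray], path, header: Mapping | None = None) -> None:
    """JASPAR-style blocks: '>id' then four rows labelled A/C/G/T."""
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        for name, pfm in pfms.items():
            pfm = np.asarray(pfm)
            fh.write(f">{name}\n")
            for base, row in zip("ACGT", pfm):
                fh.write(base + "\t" + "\t".join(format(v, "g") for v in row) + "\n")


def read_pfms(path) -> dict[str, np.ndarray]:
    pfms: dict[str, np.ndarray] = {}
    name, rows = None, []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.startswith(">"):
                if name is not None and len(rows) != 4:
                    raise ParseError(path, i, f"motif {name!r} has {len(rows)} rows, expected 4")
                if name is not None:
                    pfms[name] = np.array(rows, dtype=float)
                name, rows = line[1:].strip(), []
            else:
                if name is None:
                    raise ParseError(path, i, "PFM row before any '>id' header")
                fields = line.split("\t")
                expected = "ACGT"[len(rows)] if len(rows) < 4 else None
                if expected is None or fields[0] != expected:
                    raise ParseError(path, i, f"expected row label {expected!r}, got {fields[0]!r}")
                rows.append([float(v) for v in fields[1:]])
    if name is not None:
        if len(rows) != 4:
            raise ParseError(path, 0, f"motif {name!r} has {len(rows)} rows, expected 4")
        pfms[name] = np.array(rows, dtype=float)
    return pfms


def write_edges(edges: Iterable[tuple[str, str]], path, header: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        fh.write("child\tparent\n")
        for child, parent in edges:
            fh.write(f"{child}\t{parent}\n")


def read_edges(path) -> list[tuple[str, str]]:
    df = _read_tsv(path, ["child", "parent"])
    return list(zip(df["child"].astype(str), df["parent"].astype(str)))


def write_annotations(annotations: Mapping[str, Iterable[str]], path,
                      header: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        fh.write("gene\tterm\n")
        for gene in annotations:
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_annotations(path) -> dict[str, set[str]]:
    df = _read_tsv(path, ["gene", "term"])
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"].astype(str), df["term"].astype(str)):
        out.setdefault(gene, set()).add(term)
    return out


def write_ranked(ranked: pd.DataFrame, path, header: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        ranked[["gene", "score"]].to_csv(fh, sep="\t", index=False)


def read_ranked(path) -> pd.DataFrame:
    df = _read_tsv(path, ["gene", "score"])
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise ParseError(path, 0, f"duplicate gene {dup!r} in ranked list")
    return df


def write_ct(ct: pd.DataFrame, path, header: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        ct[["sample", "gene", "condition", "ct"]].to_csv(fh, sep="\t", index=False)


def read_ct(path) -> pd.DataFrame:
    df = _read_tsv(path, ["sample", "gene", "condition", "ct"])
    if (df["ct"] <= 0).any():
        raise ParseError(path, 0, "Ct values must be positive")
    return df
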