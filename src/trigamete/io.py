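"""Genotype file I/O (MAPMAKER/EXP-style .raw dialect and plain TSV) and the
published worked-example gamete-frequency table used by the tests.

The .raw dialect::

    data type f2 codominant
    333 6
    *marker1 AHB-A...
    *marker2 ...

Codominant codes map A -> 0 (homozygote, parent A), B -> 1, H -> 2
(heterozygote), '-' -> missing.  Dominant files use the same letters with B
read as H (the heterozygote and the B homozygote share the dominant
phenotype), so A is the recessive class and H the dominant class.

All writes are atomic (temp file + rename), so interrupted runs never leave
truncated outputs.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    DOMINANT,
    GenotypeDataError,
    GenotypeMatrix,
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    NormalizedGameteFreqs,
    RECESSIVE,
    ThetaMatrix,
    validate_matrix,
)

__all__ = [
    "read_raw",
    "write_raw",
    "read_tsv",
    "write_tsv",
    "write_theta_tsv",
    "table3_fixture",
]

_CODOMINANT_IN = {"A": HOM_A, "B": HOM_B, "H": HET, "-": MISSING}
_DOMINANT_IN = {"A": RECESSIVE, "B": DOMINANT, "H": DOMINANT, "-": MISSING}
_CODOMINANT_OUT = {HOM_A: "A", HOM_B: "B", HET: "H", MISSING: "-"}
_DOMINANT_OUT = {RECESSIVE: "A", DOMINANT: "H", MISSING: "-"}


def _atomic_write(path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_raw(path) -> GenotypeMatrix:
    """Parse a .raw genotype file; errors carry line numbers."""
    lines = Path(path).read_text().splitlines()
    content = [(i + 1, ln.strip()) for i, ln in enumerate(lines) if ln.strip()]
    if len(content) < 2:
        raise GenotypeDataError(f"{path}: truncated file (no header)")
    lineno, header = content[0]
    parts = header.split()
    if len(parts) < 4 or parts[0] != "data" or parts[1] != "type":
        raise GenotypeDataError(f"{path}:{lineno}: bad header line {header!r}")
    marker_type = parts[3]
    if marker_type == "intercross":  # stock MAPMAKER/EXP header
        marker_type = "codominant"
    if marker_type not in ("dominant", "codominant"):
        raise GenotypeDataError(f"{path}:{lineno}: unknown data type {marker_type!r}")
    lineno, counts = content[1]
    try:
        n_ind, n_mark = (int(x) for x in counts.split()[:2])
    except ValueError:
        raise GenotypeDataError(f"{path}:{lineno}: bad count line {counts!r}") from None
    table = _CODOMINANT_IN if marker_type == "codominant" else _DOMINANT_IN

    names, columns = [], []
    for lineno, line in content[2:]:
        if not line.startswith("*"):
            raise GenotypeDataError(f"{path}:{lineno}: expected '*marker' line")
        fields = line[1:].split()
        if len(fields) < 2:
            raise GenotypeDataError(f"{path}:{lineno}: marker line without codes")
        name, codes = fields[0], "".join(fields[1:])
        if len(codes) != n_ind:
            raise GenotypeDataError(
                f"{path}:{lineno}: marker {name!r} has {len(codes)} codes, "
                f"expected {n_ind}"
            )
        col = np.empty(n_ind, dtype=np.int8)
        for i, ch in enumerate(codes):
            if ch not in table:
                raise GenotypeDataError(
                    f"{path}:{lineno}: illegal code {ch!r} for individual {i} "
                    f"at marker {name!r}"
                )
            col[i] = table[ch]
        names.append(name)
        columns.append(col)
    if len(names) != n_mark:
        raise GenotypeDataError(
            f"{path}: header declares {n_mark} markers, found {len(names)}"
        )
    matrix = GenotypeMatrix(
        calls=np.column_stack(columns), markers=names, marker_type=marker_type
    )
    return validate_matrix(matrix)


def write_raw(matrix: GenotypeMatrix, path) -> None:
    """Lossless serialization to the .raw dialect (atomic)."""
    if matrix.n_individuals == 0 or matrix.n_markers == 0:
        raise GenotypeDataError("refusing to write an empty matrix")
    validate_matrix(matrix)
    table = _CODOMINANT_OUT if matrix.marker_type == "codominant" else _DOMINANT_OUT
    out = [
        f"data type f2 {matrix.marker_type}",
        f"{matrix.n_individuals} {matrix.n_markers}",
    ]
    for j, name in enumerate(matrix.markers):
        codes = "".join(table[int(c)] for c in matrix.calls[:, j])
        out.append(f"*{name} {codes}")
    _atomic_write(path, "\n".join(out) + "\n")


def read_tsv(path) -> GenotypeMatrix:
    """Read the TSV alternative: individuals as rows, markers as columns.

    The first line must be a ``# marker_type: <type>`` comment.
    """
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("# marker_type:"):
        raise GenotypeDataError(f"{path}: missing '# marker_type:' comment line")
    marker_type = first.split(":", 1)[1].strip()
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    table = _CODOMINANT_IN if marker_type == "codominant" else _DOMINANT_IN
    calls = np.empty(df.shape, dtype=np.int8)
    for j, col in enumerate(df.columns):
        for i, ch in enumerate(df[col]):
            if ch not in table:
                raise GenotypeDataError(
                    f"{path}: illegal code {ch!r} at individual {df.index[i]!r}, "
                    f"marker {col!r}"
                )
            calls[i, j] = table[ch]
    matrix = GenotypeMatrix(
        calls=calls, markers=list(df.columns), marker_type=marker_type
    )
    return validate_matrix(matrix)


def write_tsv_matrix(matrix: GenotypeMatrix, path) -> None:
    """TSV serialization (individuals as rows), atomic."""
    if matrix.n_individuals == 0 or matrix.n_markers == 0:
        raise GenotypeDataError("refusing to write an empty matrix")
    validate_matrix(matrix)
    table = _CODOMINANT_OUT if matrix.marker_type == "codominant" else _DOMINANT_OUT
    rows = ["\t".join(["individual"] + list(matrix.markers))]
    for i in range(matrix.n_individuals):
        rows.append(
            "\t".join([str(i + 1)] + [table[int(c)] for c in matrix.calls[i]])
        )
    text = f"# marker_type: {matrix.marker_type}\n" + "\n".join(rows) + "\n"
    _atomic_write(path, text)


def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    """Atomic TSV dump of a results table."""
    _atomic_write(path, frame.to_csv(sep="\t", index=index))


def write_theta_tsv(theta: ThetaMatrix, path) -> None:
    """Symmetric pairwise-theta TSV with markers on both axes."""
    write_tsv(theta.to_frame(), path, index=True)


# Published normalized gamete frequencies (p1 = f(abc), p2 = f(Abc),
# p3 = f(abC), p4 = f(aBc)) of the four linked dominant triples among mouse
# RFLP loci 1, 2, 3 and 5 (333 F2 mice), as estimated by ELS.  Used by the
# worked-example tests and the acceptance pipeline.
_TABLE3 = {
    ("1", "2", "3"): (0.208668, 0.086162, 0.094698, 0.110472),
    ("1", "2", "5"): (0.200976, 0.080676, 0.108494, 0.109854),
    ("1", "3", "5"): (0.209093, 0.065783, 0.122370, 0.102753),
    ("2", "3", "5"): (0.202566, 0.085775, 0.112098, 0.099561),
}


def table3_fixture() -> dict[tuple[str, str, str], NormalizedGameteFreqs]:
    """The worked example's four normalized gamete-frequency vectors."""
    return {
        triple: NormalizedGameteFreqs(p=np.array(p), locus_ids=triple)
        for triple, p in _TABLE3.items()
    }
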