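"""Readers and writers for alignments, character matrices, and results."""

from __future__ import annotations

import json
import pathlib

import numpy as np

from .models import NUC_STATES
from .synthetic import MISSING, Alignment, CharacterMatrix

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_nexus_alignment",
    "write_nexus_characters",
    "read_nexus_characters",
    "write_characters_csv",
    "read_characters_csv",
    "write_fit_json",
    "write_results_tsv",
]

_NUC_CODE = {c: i for i, c in enumerate(NUC_STATES)}


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(aln.taxa, aln.sequence_strings()):
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path) -> Alignment:
    taxa, seqs, cur = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                taxa.append(line[1:].split()[0])
                if cur:
                    seqs.append("".join(cur))
                cur = []
            else:
                cur.append(line.upper())
    if cur:
        seqs.append("".join(cur))
    if len(taxa) != len(seqs):
        raise ValueError("malformed FASTA")
    states = np.array([[_NUC_CODE[c] for c in s] for s in seqs], dtype=np.int8)
    return Alignment(tuple(taxa), states)


def write_nexus_alignment(aln: Alignment, path) -> None:
    seqs = aln.sequence_strings()
    pad = max(len(t) for t in aln.taxa) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(aln.taxa)} NCHAR={aln.length};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
        for name, seq in zip(aln.taxa, seqs):
            fh.write(f"    {name:<{pad}}{seq}\n")
        fh.write("  ;\nEND;\n")


def _char_symbol(s: int) -> str:
    return "?" if s == MISSING else str(s)


def write_nexus_characters(m: CharacterMatrix, path) -> None:
    pad = max(len(t) for t in m.taxa) + 2
    symbols = "".join(str(i) for i in range(m.k_states))
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(m.taxa)} NCHAR={m.n_chars};\n")
        fh.write(f'  FORMAT DATATYPE=STANDARD MISSING=? SYMBOLS="{symbols}";\n  MATRIX\n')
        for i, name in enumerate(m.taxa):
            row = "".join(_char_symbol(s) for s in m.states[i])
            fh.write(f"    {name:<{pad}}{row}\n")
        fh.write("  ;\nEND;\n")


def read_nexus_characters(path) -> CharacterMatrix:
    """Minimal reader for the STANDARD-datatype matrices written above."""
    taxa, rows = [], []
    in_matrix = False
    k = 2
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.upper().startswith("FORMAT") and "SYMBOLS" in s.upper():
                sym = s.split('"')[1]
                k = len(sym)
            if s.upper().startswith("MATRIX"):
                in_matrix = True
                continue
            if in_matrix:
                if s.startswith(";"):
                    break
                if not s:
                    continue
                parts = s.split()
                taxa.append(parts[0])
                rows.append([MISSING if c == "?" else int(c) for c in parts[1]])
    return CharacterMatrix(tuple(taxa), np.array(rows, dtype=np.int8), k)


def write_characters_csv(m: CharacterMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon," + ",".join(f"char{i + 1}" for i in range(m.n_chars)) + "\n")
        for i, name in enumerate(m.taxa):
            fh.write(name + "," + ",".join(_char_symbol(s) for s in m.states[i]) + "\n")


def read_characters_csv(path, k_states: int = None) -> CharacterMatrix:
    taxa, rows = [], []
    with open(path) as fh:
        next(fh)
        for line in fh:
            parts = line.strip().split(",")
            if not parts[0]:
                continue
            taxa.append(parts[0])
            rows.append([MISSING if c == "?" else int(c) for c in parts[1:]])
    states = np.array(rows, dtype=np.int8)
    if k_states is None:
        k_states = int(states.max()) + 1
    return CharacterMatrix(tuple(taxa), states, k_states)


def write_fit_json(fit, path) -> None:
    payload = {
        "log_likelihood": fit.log_likelihood,
        "n_free_params": fit.n_free_params,
        "n_columns": fit.n_columns,
        "proportionality_constant": fit.proportionality_constant,
        "converged": fit.converged,
        "branch_lengths": {k: list(map(float, v)) for k, v in fit.branch_lengths.items()},
    }
    pathlib.Path(path).write_text(json.dumps(payload, indent=2))


def write_results_tsv(results, path) -> None:
    """One line per TestResult: method, statistic, p/criterion, detected."""
    with open(path, "w") as fh:
        fh.write("method\tstatistic\tp_value\tdetected\tn_points\n")
        for r in results:
            p = "" if r.p_value is None else f"{r.p_value:.6g}"
            fh.write(f"{r.method}\t{r.statistic:.6g}\t{p}\t{int(r.detected)}\t{r.n_points}\n")
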