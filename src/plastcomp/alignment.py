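"""Global pairwise alignment with affine gap costs (Gotoh), plus import/export
of aligned FASTA and MAFFT-backed multiple alignment for >2 sequences.

Scoring defaults: match +2, mismatch -3, gap open -8 (charged on the first
gapped base), gap extend -1 per additional base.  The DP is vectorised per
row with numpy; the horizontal gap state is resolved with a prefix-max trick
so no inner Python loop runs over columns.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import FormatError

MAX_PAIR_LEN = 20000

NEG = -(10 ** 9)


@dataclass
class Scoring:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -8      # cost of the first base of a gap
    gap_extend: int = -1    # cost of each additional base


@dataclass
class Alignment:
    rows: list[str]
    labels: list[str] = field(default_factory=list)
    score: float | None = None

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 rows")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("alignment rows differ in length")
        if not self.labels:
            self.labels = [f"seq{i}" for i in range(len(self.rows))]
        for col in range(L):
            if all(r[col] == "-" for r in self.rows):
                raise ValueError(f"all-gap column at {col}")

    @property
    def aligned_length(self) -> int:
        return len(self.rows[0])


def align_pair(a: str, b: str, scoring: Scoring | None = None,
               labels: tuple[str, str] = ("a", "b")) -> Alignment:
    """Optimal global alignment of two sequences under affine gap costs."""
    sc = scoring or Scoring()
    if not a or not b:
        raise ValueError("empty sequence")
    if len(a) > MAX_PAIR_LEN or len(b) > MAX_PAIR_LEN:
        raise ValueError(
            f"sequence over {MAX_PAIR_LEN} bp: align region-wise or import an "
            "external alignment"
        )
    la, lb = len(a), len(b)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    go, ge = sc.gap_open, sc.gap_extend
    ks = np.arange(lb, dtype=np.int64)
    js = np.arange(1, lb + 1, dtype=np.int64)

    M = np.full(lb + 1, NEG, dtype=np.int64)   # both residues aligned
    X = np.full(lb + 1, NEG, dtype=np.int64)   # gap in b (vertical move)
    Y = np.full(lb + 1, NEG, dtype=np.int64)   # gap in a (horizontal move)
    M[0] = 0
    Y[1:] = go + (js - 1) * ge
    # traceback codes, packed one byte per cell to keep 20 kb inputs in
    # memory: bits 0-1 tbM (predecessor state of the diagonal step),
    # bits 2-3 tbX, bits 4-5 tbY (1 = gap extend, 0 = open from M,
    # 2/3 = open from the other gap state)
    tb = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    tb[0, 1:] |= np.uint8(1 << 4)
    tb[0, 1] &= np.uint8(~(3 << 4) & 0xFF)

    for i in range(1, la + 1):
        Mp, Xp, Yp = M, X, Y
        # vertical gap: open from max(M, Y) of the row above, or extend X
        open_from = np.where(Mp >= Yp, Mp, Yp)
        open_code = np.where(Mp >= Yp, 0, 2).astype(np.uint8)
        ox = open_from + go
        ex = Xp + ge
        X = np.maximum(ox, ex)
        row_tb = np.where(ex > ox, 1, open_code).astype(np.uint8) << 2
        # diagonal step
        stack = np.stack([Mp[:-1], Xp[:-1], Yp[:-1]])
        M = np.full(lb + 1, NEG, dtype=np.int64)
        sub_row = np.where(aa[i - 1] == bb, sc.match, sc.mismatch)
        M[1:] = stack.max(axis=0) + sub_row
        row_tb[1:] |= stack.argmax(axis=0).astype(np.uint8)
        # horizontal gap: Y[j] = max(B[j-1]+go, Y[j-1]+ge), B = max(M, X),
        # resolved in one shot with a prefix max over B[k] - k*ge
        B = np.maximum(M, X)
        run = np.maximum.accumulate(B[:-1] - ks * ge)
        Y = np.full(lb + 1, NEG, dtype=np.int64)
        Y[1:] = run + go + (js - 1) * ge
        open_y = B[:-1] + go
        code_y = np.where(M[:-1] >= X[:-1], 0, 3).astype(np.uint8)
        row_tb[1:] |= np.where(Y[1:] > open_y, 1, code_y).astype(np.uint8) << 4
        row_tb[0] |= np.uint8(1 << 4)
        tb[i] = row_tb

    finals = (M[lb], X[lb], Y[lb])
    st = int(np.argmax(finals))
    score = float(finals[st])
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    while i > 0 or j > 0:
        if st == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            st = int(tb[i, j] & 3)
            i -= 1
            j -= 1
        elif st == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            code = int((tb[i, j] >> 2) & 3)
            i -= 1
            st = 1 if code == 1 else (0 if code == 0 else 2)
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            code = int((tb[i, j] >> 4) & 3)
            j -= 1
            st = 2 if code == 1 else (0 if code == 0 else 1)
    return Alignment(
        rows=["".join(reversed(out_a)), "".join(reversed(out_b))],
        labels=list(labels),
        score=score,
    )


def read_aligned_fasta(path: str | Path) -> Alignment:
    """Import an externally produced aligned FASTA (e.g. MAFFT output)."""
    labels, rows, cur = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if cur:
                    rows.append("".join(cur))
                    cur = []
                labels.append(line[1:].split()[0])
            elif line:
                cur.append(line.upper())
    if cur:
        rows.append("".join(cur))
    if not rows:
        raise FormatError(f"{path}: no aligned sequences")
    return Alignment(rows=rows, labels=labels)


def write_aligned_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for label, row in zip(aln.labels, aln.rows):
            fh.write(f">{label}\n")
            for i in range(0, len(row), 70):
                fh.write(row[i : i + 70] + "\n")


def align_multi(seqs: dict[str, str]) -> Alignment:
    """Multiple alignment of >= 2 sequences.

    Two sequences go through the internal pairwise aligner; more are aligned
    with MAFFT (the standard tool for this step) when available.
    """
    items = list(seqs.items())
    if len(items) < 2:
        raise ValueError("need >= 2 sequences")
    if len(items) == 2:
        (la, sa), (lb, sb) = items
        aln = align_pair(sa, sb)
        aln.labels = [la, lb]
        return aln
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH for multiple alignment")
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        with open(fin, "w") as fh:
            for label, s in items:
                fh.write(f">{label}\n{s}\n")
        res = subprocess.run(
            ["mafft", "--auto", "--quiet", str(fin)],
            capture_output=True, text=True, check=True,
        )
        fout = Path(tmp) / "out.fasta"
        fout.write_text(res.stdout)
        aln = read_aligned_fasta(fout)
    # restore input order
    order = {label: i for i, label in enumerate(aln.labels)}
    aln_rows = [aln.rows[order[label]] for label, _ in items]
    return Alignment(rows=aln_rows, labels=[label for label, _ in items])
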