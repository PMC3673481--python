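"""Genepop text format reader/writer.

Genepop is the standard interchange format for population genotype data:
a title line, one locus name per line (or a single comma-separated line),
then one ``POP`` block per sampling site with lines

    <individual name> ,  <a1a2> <a1a2> ...

where each token concatenates the two allele codes of a diploid genotype
in fixed width (2- or 3-digit), with ``00``/``000`` meaning a missing
allele.  We write the 3-digit dialect and auto-detect 2- vs 3-digit on
read from the token length.
"""

from __future__ import annotations


import numpy as np

from .core import GenotypeTable


class GenepopFormatError(ValueError):
    """Raised when a Genepop file cannot be parsed."""


def _detect_width(token: str, lineno: int) -> int:
    if len(token) % 2:
        raise GenepopFormatError(
            f"line {lineno}: genotype token '{token}' has odd length"
        )
    width = len(token) // 2
    if width not in (2, 3):
        raise GenepopFormatError(
            f"line {lineno}: genotype token '{token}' is neither 2- nor 3-digit"
        )
    return width


def read_genepop(path) -> GenotypeTable:
    """Parse a Genepop file into a :class:`GenotypeTable`.

    Sites are labelled ``POP1 .. POPk`` in file order unless the first
    individual name of a block is usable as a label (the common Genepop
    convention of naming individuals ``<site>_<k>`` or repeating the site
    name); the label used is the part of the first individual's name
    before the last ``_``, falling back to ``POP<k>``.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopFormatError("empty file")

    # locus names: everything between the title line and the first POP
    locus_names: list[str] = []
    body_start = None
    for i, line in enumerate(lines[1:], start=2):
        if line.strip().upper() == "POP":
            body_start = i - 1
            break
        stripped = line.strip()
        if stripped:
            if "," in stripped:
                locus_names.extend(t.strip() for t in stripped.split(",") if t.strip())
            else:
                locus_names.append(stripped)
    if body_start is None:
        raise GenepopFormatError("no POP blocks found")
    if not locus_names:
        raise GenepopFormatError("no locus names found")

    L = len(locus_names)
    ids: list[str] = []
    site_of: list[str] = []
    rows: list[np.ndarray] = []
    width: int | None = None
    pop_idx = 0
    current_site: str | None = None

    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.upper() == "POP":
            pop_idx += 1
            current_site = None
            continue
        if pop_idx == 0:
            raise GenepopFormatError(f"line {lineno}: data before first POP")
        if "," not in stripped:
            raise GenepopFormatError(f"line {lineno}: missing ',' separator")
        name, _, geno_part = stripped.partition(",")
        name = name.strip()
        tokens = geno_part.split()
        if len(tokens) != L:
            raise GenepopFormatError(
                f"line {lineno}: expected {L} genotype tokens, got {len(tokens)}"
            )
        if current_site is None:
            current_site = name.rsplit("_", 1)[0] if "_" in name else f"POP{pop_idx}"
        row = np.zeros((L, 2), dtype=np.int32)
        for j, tok in enumerate(tokens):
            if not tok.isdigit():
                raise GenepopFormatError(
                    f"line {lineno}: non-numeric genotype token '{tok}'"
                )
            w = _detect_width(tok, lineno)
            if width is None:
                width = w
            elif w != width:
                raise GenepopFormatError(
                    f"line {lineno}: token '{tok}' width differs from "
                    f"{2 * width}-digit dialect detected earlier"
                )
            a1, a2 = int(tok[:w]), int(tok[w:])
            if (a1 == 0) != (a2 == 0):
                raise GenepopFormatError(
                    f"line {lineno}: half-missing genotype '{tok}'"
                )
            row[j] = (a1, a2)
        ids.append(name)
        site_of.append(current_site)
        rows.append(row)

    if not rows:
        raise GenepopFormatError("no individuals found")
    # de-duplicate inferred site labels that collide across blocks
    seen: dict[str, int] = {}
    final_sites = list(site_of)
    genotypes = np.stack(rows)
    return GenotypeTable(ids, np.array(final_sites, dtype=object), genotypes, locus_names)


def write_genepop(table: GenotypeTable, path, title: str = "seapop export") -> None:
    """Write a table in the 3-digit Genepop dialect, one POP block per site."""
    if table.n_loci == 0:
        raise GenepopFormatError("cannot write a table with no loci")
    if np.any(table.genotypes > 999):
        raise ValueError("allele codes above 999 cannot be written in 3-digit Genepop")
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for name in table.locus_names:
            fh.write(name + "\n")
        for site in table.site_labels:
            fh.write("POP\n")
            for i in table.site_indices(site):
                toks = [
                    f"{a1:03d}{a2:03d}" for a1, a2 in table.genotypes[i]
                ]
                fh.write(f"{table.individual_ids[i]} ,  " + " ".join(toks) + "\n")
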