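"""Shared fixtures: printed oligo sequences, small tag sets, PDB text builders."""

from __future__ import annotations

import pytest

from starbind.sequences import NucleotideSequence, TagSet

# RNA oligonucleotides as printed in the binding tables
G8_5 = "CUGGGUGACACACUAGCUAUAGCAUUAAAAGACCGAGCAAGU"
G7_1 = "UCCGGAUUGGCCUAAAUAGAUGCGCGAUAAUAAUAGAGUA"
SRE4 = "UUUGGGGGUUCAAUAAAAAUUUUCACUAUCCUAUUAACAGUUCCGCCGCUCC"
NRXN2 = "CCCAAUUAACUAACUAACUAACUUUAAAA"


def linker_construct(n_c: int) -> str:
    """UAAA-Cn-UAAA: two UAAA sites joined by a poly-C linker of n cytosines."""
    return "UAAA" + "C" * n_c + "UAAA"


@pytest.fixture
def oligos() -> dict[str, str]:
    return {"G8.5": G8_5, "G7.1": G7_1, "SRE-4": SRE4, "Nrxn2": NRXN2}


@pytest.fixture
def tagset_factory():
    def make(sequences: list[str], name: str = "test") -> TagSet:
        return TagSet(
            name=name,
            sequences=[NucleotideSequence(f"s{i}", s) for i, s in enumerate(sequences)],
        )

    return make


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    x: float,
    y: float,
    z: float,
    element: str,
    altloc: str = " ",
    record: str = "ATOM",
) -> str:
    """One fixed-column PDB ATOM/HETATM line."""
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"{record:<6s}{serial:>5d} {name_field}{altloc}{resname:>3s} {chain}"
        f"{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def pdb_writer(tmp_path):
    def write(lines: list[str], filename: str = "model.pdb"):
        path = tmp_path / filename
        path.write_text("\n".join(lines) + "\n")
        return path

    return write
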