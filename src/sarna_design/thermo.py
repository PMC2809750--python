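"""Duplex end-stability from nearest-neighbor stacking parameters.

Functional saRNA duplexes need the 3' end of the target (= 5' end of the
guide strand) to be thermodynamically weaker than the 5' end, so that
the guide strand is preferentially loaded. "Stability" of a terminal
window is operationalised as the sum of nearest-neighbor stacking
free energies (kcal/mol, 37 C) over its consecutive dinucleotides,
assuming a fully Watson-Crick paired duplex. Initiation terms are
omitted: only the 3' - 5' difference (the asymmetry) is ever compared,
and initiation contributes equally to both ends. An optional terminal
A-U penalty can be charged at each window's outer duplex terminus.

The default parameter set is the Xia/Turner 1998 RNA table shipped with
the package; a SantaLucia 1998 DNA table is selectable for comparison.
Both are plain-text, loadable and dumpable through this module.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

from .sequence_core import dna_to_rna

BUILTIN_TABLES = {
    "rna_xia_turner_1998": "xia_turner_1998_rna.tsv",
    "dna_santalucia_1998": "santalucia_1998_dna.tsv",
}


class ThermoConfigError(ValueError):
    pass


@dataclass(frozen=True)
class NNTable:
    """A nearest-neighbor stacking parameter set.

    ``stacks`` maps each 5'->3' sense-strand dinucleotide to its stacking
    free energy in kcal/mol (more negative = more stable).
    """

    name: str
    alphabet: str  # "rna" or "dna"
    stacks: dict[str, float]
    terminal_au_penalty: float = 0.0

    def __post_init__(self) -> None:
        if self.alphabet not in ("rna", "dna"):
            raise ThermoConfigError(f"alphabet must be rna/dna, got {self.alphabet!r}")

    @property
    def weak_bases(self) -> frozenset[str]:
        return frozenset("AU") if self.alphabet == "rna" else frozenset("AT")


def load_nn_table(source: str | Path) -> NNTable:
    """Load a parameter table from a built-in name or a file path.

    File format: ``# key: value`` header lines naming the set, alphabet,
    units and terminal penalty, then whitespace-separated
    ``dinucleotide value`` rows.
    """
    if isinstance(source, str) and source in BUILTIN_TABLES:
        ref = importlib.resources.files("sarna_design") / "data" / BUILTIN_TABLES[source]
        text = ref.read_text()
    else:
        text = Path(source).read_text()
    meta: dict[str, str] = {}
    stacks: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ThermoConfigError(f"malformed table row: {line!r}")
        stacks[fields[0].upper()] = float(fields[1])
    return NNTable(
        name=meta.get("nn_set", "unnamed"),
        alphabet=meta.get("alphabet", "rna"),
        stacks=stacks,
        terminal_au_penalty=float(meta.get("terminal_au_penalty", 0.0)),
    )


def dump_nn_table(table: NNTable, path: str | Path) -> None:
    """Write a table in the same plain-text format loaded by load_nn_table."""
    with open(path, "w") as fh:
        fh.write(f"# nn_set: {table.name}\n")
        fh.write(f"# alphabet: {table.alphabet}\n")
        fh.write("# units: kcal/mol (delta-G at 37 C, Watson-Crick stacks)\n")
        fh.write(f"# terminal_au_penalty: {table.terminal_au_penalty}\n")
        fh.write("# key: 5'->3' dinucleotide on the sense strand of the duplex\n")
        for stack in sorted(table.stacks):
            fh.write(f"{stack}\t{table.stacks[stack]}\n")


def nn_free_energy(duplex_seq: str, params: NNTable) -> float:
    """Stacking free energy (kcal/mol) of a fully paired duplex.

    Sum of stacked-pair parameters over consecutive dinucleotides of the
    sense strand; no initiation or terminal terms.
    """
    seq = duplex_seq.upper()
    if len(seq) < 2:
        raise ValueError("nearest-neighbor energy needs at least 2 bases")
    total = 0.0
    for i in range(len(seq) - 1):
        stack = seq[i : i + 2]
        try:
            total += params.stacks[stack]
        except KeyError:
            raise ThermoConfigError(
                f"dinucleotide {stack!r} absent from table {params.name!r}"
            ) from None
    return total


@dataclass(frozen=True)
class EndStability:
    """Free-energy proxies of a target's terminal duplex windows.

    ``asymmetry = dg_3p - dg_5p``; positive means the 3' end is the less
    stable one (the desired guide-selection bias).
    """

    dg_5p: float
    dg_3p: float
    k: int

    @property
    def asymmetry(self) -> float:
        return self.dg_3p - self.dg_5p


def end_stability(
    target_dna: str,
    k: int = 5,
    params: NNTable | None = None,
    include_terminal_au: bool = False,
) -> EndStability:
    """End stabilities of a 19-nt DNA target's first and last k bases.

    The target is converted to the sense-strand alphabet of ``params``
    (RNA by default — the functional molecule is an RNA duplex). With
    ``include_terminal_au`` the table's terminal penalty is charged when
    the window's outer duplex terminus (position 1 for the 5' window,
    the last position for the 3' window) is a weak A-U/A-T pair.
    Overhangs are never part of the windows: only paired bases count.
    """
    if params is None:
        params = load_nn_table("rna_xia_turner_1998")
    seq = dna_to_rna(target_dna) if params.alphabet == "rna" else target_dna.upper()
    if not 2 <= k <= len(seq):
        raise ValueError(f"k must be in [2, {len(seq)}], got {k}")
    dg_5p = nn_free_energy(seq[:k], params)
    dg_3p = nn_free_energy(seq[-k:], params)
    if include_terminal_au:
        if seq[0] in params.weak_bases:
            dg_5p += params.terminal_au_penalty
        if seq[-1] in params.weak_bases:
            dg_3p += params.terminal_au_penalty
    return EndStability(dg_5p=dg_5p, dg_3p=dg_3p, k=k)


def passes_asymmetry(es: EndStability, margin: float = 0.0) -> bool:
    """True iff the 3' end is strictly less stable than the 5' end by
    more than ``margin`` kcal/mol (equality carries no strand-selection
    information, so it does not pass)."""
    return es.asymmetry > margin
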