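"""The 31-gene immune-checkpoint panel with role and class annotations.

The panel covers the costimulatory and coinhibitory ligands and receptors
commonly assayed in gastric-cancer immune profiling.  Each entry carries two
orthogonal annotations: role (ligand vs receptor on the immune synapse) and
class (costimulatory vs coinhibitory signalling).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ICGEntry", "ICGRegistry", "load_icg_registry"]

_COSTIMULATORY = {
    "CD27", "CD28", "CD40", "CD40LG", "ICOS", "ICOSLG",
    "TNFRSF18", "TNFRSF4", "TNFRSF9", "TNFSF18", "TNFSF4", "TNFSF9",
}
_COINHIBITORY = {
    "ADORA2A", "BTLA", "CD160", "CD274", "CD276", "CD70", "CD80", "CD86",
    "CTLA4", "HAVCR2", "KIR3DL1", "LAG3", "LGALS9", "PDCD1", "PDCD1LG2",
    "TNFRSF14", "TNFSF14", "VSIR", "VTCN1",
}
_LIGANDS = {
    "CD160", "CD274", "CD276", "CD40LG", "CD70", "CD80", "CD86", "ICOSLG",
    "LGALS9", "PDCD1LG2", "TNFRSF14", "TNFSF14", "TNFSF18", "TNFSF4",
    "TNFSF9", "VSIR", "VTCN1",
}
_RECEPTORS = {
    "ADORA2A", "BTLA", "CD27", "CD28", "CD40", "CTLA4", "HAVCR2", "ICOS",
    "KIR3DL1", "LAG3", "PDCD1", "TNFRSF18", "TNFRSF4", "TNFRSF9",
}


@dataclass(frozen=True)
class ICGEntry:
    gene_symbol: str
    role: str  # "ligand" | "receptor"
    cls: str  # "costimulatory" | "coinhibitory"


@dataclass(frozen=True)
class ICGRegistry:
    entries: tuple[ICGEntry, ...]

    @property
    def genes(self) -> list[str]:
        return [e.gene_symbol for e in self.entries]

    def __getitem__(self, gene: str) -> ICGEntry:
        for e in self.entries:
            if e.gene_symbol == gene:
                return e
        raise KeyError(gene)

    def __len__(self) -> int:
        return len(self.entries)

    def by_role(self, role: str) -> list[str]:
        return [e.gene_symbol for e in self.entries if e.role == role]

    def by_class(self, cls: str) -> list[str]:
        return [e.gene_symbol for e in self.entries if e.cls == cls]


def load_icg_registry() -> ICGRegistry:
    """Build the packaged 31-gene immune-checkpoint registry.

    Integrity invariants (31 unique genes; ligand/receptor and
    costimulatory/coinhibitory annotations each partition the panel) are
    asserted at load time.
    """
    genes = sorted(_COSTIMULATORY | _COINHIBITORY)
    entries = []
    for g in genes:
        role = "ligand" if g in _LIGANDS else "receptor"
        cls = "costimulatory" if g in _COSTIMULATORY else "coinhibitory"
        entries.append(ICGEntry(g, role, cls))
    reg = ICGRegistry(tuple(entries))

    assert len(reg) == 31, "panel must contain exactly 31 genes"
    assert len(set(reg.genes)) == 31, "gene symbols must be unique"
    assert _LIGANDS <= set(genes) and _RECEPTORS <= set(genes)
    assert not (_LIGANDS & _RECEPTORS), "role annotations must partition"
    assert not (_COSTIMULATORY & _COINHIBITORY), "class annotations must partition"
    assert len(reg.by_role("ligand")) + len(reg.by_role("receptor")) == 31
    assert len(reg.by_class("costimulatory")) + len(reg.by_class("coinhibitory")) == 31
    return reg
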