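"""Cre/loxPsym recombination products and eccDNA inheritance dynamics.

Because the loxPsym spacer is symmetric, Cre recombines any pair of sites
in either relative orientation, so every unordered site pair yields both
an excision (a circle plus a residual molecule) and an inversion; in a
sister-chromatid model a pair can also yield a duplication. A circle
carrying an autonomously replicating sequence (ARS) can propagate -- a
SCRaMbLE-produced extrachromosomal circle (SPecc). Circles without an ARS
cannot replicate and dilute out of a dividing population.

The inheritance simulator is phenomenological: per division, copies
replicate (doubled when ARS-driven), then each copy independently stays
in the mother with probability ``a`` (segregation bias); optional
selection favors carriers. It reproduces the qualitative behaviors seen
with fluorescent-reporter SPeccs -- uneven inheritance, variable copy
number, enrichment under selection -- without claiming fitted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class EccError(ValueError):
    pass


@dataclass(frozen=True)
class Element:
    id: str
    cls: str        # gene | ARS | reporter | marker | spacer
    length: int = 1
    orientation: str = "+"

    def __post_init__(self):
        if self.cls not in ("gene", "ARS", "reporter", "marker", "spacer"):
            raise EccError(f"bad element class {self.cls!r}")

    def flipped(self) -> "Element":
        return Element(self.id, self.cls, self.length,
                       "-" if self.orientation == "+" else "+")


#: sentinel item marking a loxPsym site in a locus item list
LOX = "loxPsym"


@dataclass
class LoxLocus:
    """An ordered molecule: elements interleaved with loxPsym sites."""
    topology: str   # linear | circular
    items: tuple    # Element instances and LOX sentinels, in order

    def __post_init__(self):
        if self.topology not in ("linear", "circular"):
            raise EccError(f"bad topology {self.topology!r}")
        object.__setattr__(self, "items", tuple(self.items))

    @property
    def lox_indices(self) -> list[int]:
        return [i for i, x in enumerate(self.items) if x == LOX]

    @property
    def elements(self) -> list[Element]:
        return [x for x in self.items if x != LOX]


@dataclass(frozen=True)
class Molecule:
    topology: str
    items: tuple

    @property
    def lox_count(self) -> int:
        return sum(1 for x in self.items if x == LOX)

    @property
    def elements(self) -> tuple:
        return tuple(x for x in self.items if x != LOX)

    def canonical(self) -> tuple:
        """Orientation/rotation-invariant key (reflection uses flipped
        orientations, mirroring how a physical molecule reads from either
        end or either face of a circle)."""
        def key(seq):
            return tuple(
                ("lox",) if x == LOX
                else (x.id, x.cls, x.length, x.orientation)
                for x in seq)

        fwd = tuple(self.items)
        rev = tuple(x if x == LOX else x.flipped() for x in reversed(fwd))
        if self.topology == "linear":
            return (self.topology, min(key(fwd), key(rev)))
        best = None
        for seq in (fwd, rev):
            for r in range(len(seq)):
                cand = key(seq[r:] + seq[:r])
                if best is None or cand < best:
                    best = cand
        return (self.topology, best)


@dataclass
class RecombinationProduct:
    site_i: int
    site_j: int
    type: str                    # excision | inversion | duplication
    molecules: tuple

    def canonical(self):
        return (self.type,
                tuple(sorted(m.canonical() for m in self.molecules)))


@dataclass
class SPecc:
    molecule: Molecule
    has_ars: bool
    has_reporter: bool
    payload_genes: tuple
    propagable: bool


def enumerate_products(locus: LoxLocus, sister_chromatid: bool = False
                       ) -> list[RecombinationProduct]:
    """All single-event Cre products over unordered loxPsym site pairs.

    Each pair yields one excision and one inversion (plus one duplication
    in sister-chromatid mode); products are canonicalized (circles rotated
    to a minimal representative) and deduplicated.
    """
    sites = locus.lox_indices
    products: list[RecombinationProduct] = []
    for a in range(len(sites)):
        for b in range(a + 1, len(sites)):
            i, j = sites[a], sites[b]
            inner = locus.items[i + 1:j]
            outer = locus.items[:i] + locus.items[j + 1:]

            circle = Molecule("circular", inner + (LOX,))
            residual = Molecule(locus.topology, outer[:i] + (LOX,) + outer[i:])
            products.append(RecombinationProduct(
                a, b, "excision", (circle, residual)))

            flipped = tuple(x if x == LOX else x.flipped()
                            for x in reversed(inner))
            inverted = Molecule(
                locus.topology,
                locus.items[:i + 1] + flipped + locus.items[j:])
            products.append(RecombinationProduct(
                a, b, "inversion", (inverted,)))

            if sister_chromatid:
                gained = Molecule(
                    locus.topology,
                    locus.items[:j] + (LOX,) + inner + locus.items[j:])
                lost = Molecule(locus.topology, outer[:i] + (LOX,) + outer[i:])
                products.append(RecombinationProduct(
                    a, b, "duplication", (gained, lost)))

    seen = set()
    out = []
    for p in products:
        key = p.canonical()
        if key in seen:
            continue
        seen.add(key)
        out.append(p)
    return out


def classify_specc(products: list[RecombinationProduct]) -> list[SPecc]:
    """Classify every circular product molecule; a circle is a propagable
    SPecc iff it carries >= 1 ARS. Linear molecules are excluded."""
    out = []
    seen = set()
    for p in products:
        for m in p.molecules:
            if m.topology != "circular":
                continue
            key = m.canonical()
            if key in seen:
                continue
            seen.add(key)
            els = m.elements
            out.append(SPecc(
                molecule=m,
                has_ars=any(e.cls == "ARS" for e in els),
                has_reporter=any(e.cls == "reporter" for e in els),
                payload_genes=tuple(e.id for e in els if e.cls == "gene"),
                propagable=any(e.cls == "ARS" for e in els)))
    return out


# ---------------------------------------------------------------------------
# inheritance simulation
# ---------------------------------------------------------------------------

@dataclass
class EccParams:
    replication: str = "ars_doubling"   # ars_doubling | none
    segregation_bias: float = 0.5       # P(copy stays in mother)
    selection: str = "none"             # none | advantage | dropout
    advantage_s: float = 0.0

    def __post_init__(self):
        if self.replication not in ("ars_doubling", "none"):
            raise EccError(f"bad replication mode {self.replication!r}")
        if not 0.0 <= self.segregation_bias <= 1.0:
            raise EccError("segregation bias must be in [0, 1]")
        if self.selection not in ("none", "advantage", "dropout"):
            raise EccError(f"bad selection model {self.selection!r}")
        if self.advantage_s < 0:
            raise EccError("advantage must be >= 0")


def simulate_inheritance(initial_copies: int, params: EccParams,
                         n_generations: int, n_lineages: int,
                         seed: int) -> pd.DataFrame:
    """Simulate eccDNA copy-number dynamics in a dividing pedigree.

    Every cell divides each generation; both mother and daughter lineages
    are tracked (the population doubles), so total copy count is exactly
    conserved when replication and selection are off. Returns one row per
    generation: population size, carrier fraction, and copy-number
    summary statistics.
    """
    if initial_copies < 0 or n_generations < 0 or n_lineages <= 0:
        raise EccError("invalid simulation sizes")
    rng = np.random.default_rng(seed)
    pop = np.full(n_lineages, initial_copies, dtype=np.int64)
    rows = [_summarize(0, pop)]
    for g in range(1, n_generations + 1):
        if params.replication == "ars_doubling":
            pop = pop * 2
        mothers = rng.binomial(pop, params.segregation_bias)
        daughters = pop - mothers
        pop = np.concatenate([mothers, daughters])
        if params.selection == "dropout":
            pop = pop[pop > 0]
        elif params.selection == "advantage" and params.advantage_s > 0:
            keep = (pop > 0) | (rng.random(len(pop))
                                < 1.0 / (1.0 + params.advantage_s))
            pop = pop[keep]
        rows.append(_summarize(g, pop))
        if len(pop) == 0:
            break
    return pd.DataFrame(rows)


def _summarize(generation: int, pop: np.ndarray) -> dict:
    n = len(pop)
    if n == 0:
        return {"generation": generation, "population": 0,
                "carrier_fraction": 0.0, "total_copies": 0,
                "mean_copies": 0.0, "var_copies": 0.0, "max_copies": 0}
    return {
        "generation": generation,
        "population": n,
        "carrier_fraction": float((pop > 0).mean()),
        "total_copies": int(pop.sum()),
        "mean_copies": float(pop.mean()),
        "var_copies": float(pop.var()),
        "max_copies": int(pop.max()),
    }


# ---------------------------------------------------------------------------
# locus description file
# ---------------------------------------------------------------------------

def read_locus(path) -> LoxLocus:
    """Read a locus description: one item per line, either ``loxPsym`` or
    ``id<TAB>class<TAB>length[<TAB>orientation]``; first line = topology."""
    items = []
    topology = "linear"
    with open(path) as fh:
        lines = [l.strip() for l in fh if l.strip() and not l.startswith("#")]
    if lines and lines[0] in ("linear", "circular"):
        topology = lines.pop(0)
    for line in lines:
        if line == LOX:
            items.append(LOX)
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise EccError(f"malformed locus line {line!r}")
        items.append(Element(parts[0], parts[1], int(parts[2]),
                             parts[3] if len(parts) > 3 else "+"))
    return LoxLocus(topology, tuple(items))


def gap1_syn_locus() -> LoxLocus:
    """The reformatted GAP1 locus layout: loxPsym sites replacing the LTRs
    that natively flank the permease gene, a fluorescent reporter beside
    it, and an ARS inside the excisable interval -- the configuration
    whose excision circle is a propagable SPecc."""
    return LoxLocus("linear", (
        Element("flank_L", "spacer", 500),
        LOX,
        Element("yEGFP", "reporter", 700),
        Element("GAP1", "gene", 1800),
        Element("ARS1116", "ARS", 200),
        LOX,
        Element("flank_R", "spacer", 500),
    ))
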