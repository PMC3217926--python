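"""Generic rule-based reaction-network engine on site-graphs.

Molecules are typed objects with named binding sites; a site may carry an
internal state (e.g. a phosphorylation flag) and at most one bond.  A species
is a connected site-graph of molecule instances living in one compartment.
Rules are pattern/transformation pairs; iterated rule application from a seed
set of species enumerates a finite mass-action reaction network.

The engine is deliberately small and exact rather than fast: complexes in the
models it serves contain at most a handful of molecules, so canonical labels
are computed by brute force over instance orderings (and over permutations of
symmetry-equivalent sites), which is trivially correct.

Conventions
-----------
* Species identity is the canonical label: two site-graphs are the same
  species iff their labels are equal (isomorphism invariance).
* The rate of a concrete reaction is ``k * multiplicity`` where the
  multiplicity counts distinct embedding combinations producing the same
  product multiset; a statistical factor 1/2 is applied when the two reactant
  patterns of a bimolecular rule are isomorphic (A+A-type collisions).
* Bonds may only be formed between two distinct complexes (no ring closure);
  a rule that would close a ring raises :class:`RuleDefinitionError`.
* A complex carries a single compartment label.  Bond formation merges
  compartments via :func:`merge_compartments`; dissociation re-homes each
  fragment via the molecules' allowed-compartment sets.
"""

from __future__ import annotations

import itertools
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SiteDef",
    "MoleculeDef",
    "Species",
    "Pattern",
    "PatternMol",
    "Rule",
    "Reaction",
    "ReactionNetwork",
    "StructuralError",
    "RuleDefinitionError",
    "NetworkExplosionError",
    "FREE",
    "BOUND",
    "WILD",
    "generate_network",
    "match",
    "apply_rule",
    "canonical_label",
    "merge_compartments",
]


class StructuralError(ValueError):
    """A species or pattern violates the site-graph invariants."""


class RuleDefinitionError(ValueError):
    """A rule refers to sites/states that do not exist or is ill-formed."""


class NetworkExplosionError(RuntimeError):
    """Species count exceeded ``max_species`` during network generation."""

    def __init__(self, max_species: int, last_rule: str):
        self.max_species = max_species
        self.last_rule = last_rule
        super().__init__(
            f"species count exceeded max_species={max_species} "
            f"(last rule applied: {last_rule})"
        )


# ---------------------------------------------------------------------------
# molecule types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteDef:
    """A named site; ``states`` empty means the site is stateless."""

    name: str
    states: tuple[str, ...] = ()

    def __post_init__(self):
        if len(set(self.states)) != len(self.states):
            raise StructuralError(f"duplicate states on site {self.name}")


@dataclass(frozen=True)
class MoleculeDef:
    """A molecule type: sites, allowed compartments, site symmetries.

    ``symmetric`` lists groups of site names that are physically
    interchangeable (e.g. the two talin-binding arms of a dimeric scaffold);
    canonicalization and pattern matching may permute sites within a group.
    """

    name: str
    sites: tuple[SiteDef, ...] = ()
    compartments: frozenset[str] = frozenset({"CP"})
    symmetric: tuple[frozenset[str], ...] = ()

    def __post_init__(self):
        names = [s.name for s in self.sites]
        if len(set(names)) != len(names):
            raise StructuralError(f"duplicate site names on molecule {self.name}")
        by_name = {s.name: s for s in self.sites}
        for group in self.symmetric:
            defs = {by_name[n].states for n in group}
            if len(defs) != 1:
                raise StructuralError(
                    f"symmetric sites on {self.name} must share a state list"
                )

    @property
    def site_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sites)

    def site(self, name: str) -> SiteDef:
        for s in self.sites:
            if s.name == name:
                return s
        raise KeyError(f"molecule {self.name} has no site {name!r}")

    def site_permutations(self) -> list[dict[str, str]]:
        """All site renamings allowed by the symmetry groups."""
        if not self.symmetric:
            return [{}]
        perms: list[dict[str, str]] = [{}]
        for group in self.symmetric:
            ordered = sorted(group)
            new_perms = []
            for assignment in itertools.permutations(ordered):
                mapping = dict(zip(ordered, assignment))
                for base in perms:
                    merged = dict(base)
                    merged.update(mapping)
                    new_perms.append(merged)
            perms = new_perms
        return perms


# ---------------------------------------------------------------------------
# concrete species
# ---------------------------------------------------------------------------

# bond value inside a Species: None (free) or (mol_index, site_name)
# bond value inside a Pattern: FREE, BOUND (bound to anything), WILD
# (unspecified), or an int bond id shared by exactly two pattern sites.
FREE = "free"
BOUND = "+"
WILD = "?"


@dataclass(frozen=True)
class Species:
    """An immutable connected complex with a canonical label.

    ``mols`` holds molecule type names; ``states[i]`` maps site name to state
    for every stateful site of molecule i; ``bonds[i]`` maps site name to the
    partner ``(mol_index, site_name)`` for every bound site.
    """

    mols: tuple[str, ...]
    states: tuple[tuple[tuple[str, str], ...], ...]
    bonds: tuple[tuple[tuple[str, tuple[int, str]], ...], ...]
    compartment: str
    label: str = field(compare=False, default="")

    def state_of(self, i: int, site: str) -> str | None:
        for s, v in self.states[i]:
            if s == site:
                return v
        return None

    def partner(self, i: int, site: str) -> tuple[int, str] | None:
        for s, v in self.bonds[i]:
            if s == site:
                return v
        return None

    def molecule_counts(self) -> Counter:
        return Counter(self.mols)

    def __len__(self) -> int:
        return len(self.mols)

    def __str__(self) -> str:  # pragma: no cover
        return self.label


class _Graph:
    """Mutable working representation used while applying rules."""

    __slots__ = ("defs", "mols", "states", "bonds", "compartment")

    def __init__(self, defs: Mapping[str, MoleculeDef], compartment: str):
        self.defs = defs
        self.mols: list[str] = []
        self.states: list[dict[str, str]] = []
        self.bonds: list[dict[str, tuple[int, str]]] = []
        self.compartment = compartment

    @classmethod
    def from_species(cls, defs: Mapping[str, MoleculeDef], sp: Species) -> "_Graph":
        g = cls(defs, sp.compartment)
        g.mols = list(sp.mols)
        g.states = [dict(st) for st in sp.states]
        g.bonds = [dict(b) for b in sp.bonds]
        return g

    def add_molecule(self, name: str, states: dict[str, str]) -> int:
        self.mols.append(name)
        self.states.append(dict(states))
        self.bonds.append({})
        return len(self.mols) - 1

    def merge(self, other: "_Graph") -> int:
        """Append ``other``'s molecules; returns the index offset."""
        off = len(self.mols)
        self.mols.extend(other.mols)
        self.states.extend(dict(s) for s in other.states)
        for b in other.bonds:
            self.bonds.append({s: (i + off, t) for s, (i, t) in b.items()})
        return off

    def add_bond(self, i: int, si: str, j: int, sj: str) -> None:
        if si in self.bonds[i] or sj in self.bonds[j]:
            raise StructuralError("site already bound")
        self.bonds[i][si] = (j, sj)
        self.bonds[j][sj] = (i, si)

    def del_bond(self, i: int, si: str) -> None:
        j, sj = self.bonds[i].pop(si)
        del self.bonds[j][sj]

    def components(self) -> list[list[int]]:
        seen: set[int] = set()
        comps = []
        for start in range(len(self.mols)):
            if start in seen:
                continue
            comp = [start]
            seen.add(start)
            stack = [start]
            while stack:
                i = stack.pop()
                for j, _ in self.bonds[i].values():
                    if j not in seen:
                        seen.add(j)
                        comp.append(j)
                        stack.append(j)
            comps.append(sorted(comp))
        return comps

    def subgraph(self, indices: Sequence[int], compartment: str) -> "_Graph":
        remap = {old: new for new, old in enumerate(indices)}
        g = _Graph(self.defs, compartment)
        for old in indices:
            g.mols.append(self.mols[old])
            g.states.append(dict(self.states[old]))
            g.bonds.append(
                {s: (remap[i], t) for s, (i, t) in self.bonds[old].items()}
            )
        return g

    # -- canonicalization ---------------------------------------------------

    def _render(self, order: Sequence[int], siteperms: Sequence[Mapping[str, str]]) -> str:
        pos = {old: new for new, old in enumerate(order)}
        bond_ids: dict[tuple[int, str], int] = {}
        next_id = 1
        parts = []
        for old in order:
            mdef = self.defs[self.mols[old]]
            perm = siteperms[old]
            toks = []
            for site in mdef.site_names:
                src = perm.get(site, site)  # content of `src` shown at `site`
                tok = site
                st = self.states[old].get(src)
                if st is not None:
                    tok += f"~{st}"
                partner = self.bonds[old].get(src)
                if partner is not None:
                    key = (old, src)
                    if key not in bond_ids:
                        j, sj = partner
                        # partner's displayed name is irrelevant for the id
                        bond_ids[key] = next_id
                        bond_ids[(j, sj)] = next_id
                        next_id += 1
                    tok += f"!{bond_ids[key]}"
                toks.append(tok)
            parts.append(f"{self.mols[old]}({','.join(toks)})")
        return "@" + self.compartment + ":" + ".".join(parts)

    def canonical(self) -> Species:
        n = len(self.mols)
        if n == 0:
            raise StructuralError("empty complex")
        # validate
        for i, name in enumerate(self.mols):
            mdef = self.defs[name]
            for site, st in self.states[i].items():
                if st not in mdef.site(site).states:
                    raise StructuralError(
                        f"state {st!r} not allowed on {name}.{site}"
                    )
            for site, (j, sj) in self.bonds[i].items():
                back = self.bonds[j].get(sj)
                if back != (i, site):
                    raise StructuralError("bond relation is not symmetric")
        if len(self.components()) != 1:
            raise StructuralError("complex is not connected")

        # candidate orderings: group molecules by name (names sorted), permute
        # within groups, and permute symmetry-equivalent sites.
        groups: dict[str, list[int]] = {}
        for i, name in enumerate(self.mols):
            groups.setdefault(name, []).append(i)
        group_orders = [
            itertools.permutations(groups[name]) for name in sorted(groups)
        ]
        per_mol_perms = [
            self.defs[self.mols[i]].site_permutations() for i in range(n)
        ]
        best: str | None = None
        best_order: tuple[int, ...] | None = None
        best_perms: tuple[Mapping[str, str], ...] | None = None
        for combo in itertools.product(*group_orders):
            order = tuple(itertools.chain.from_iterable(combo))
            for perms in itertools.product(*per_mol_perms):
                s = self._render(order, perms)
                if best is None or s < best:
                    best, best_order, best_perms = s, order, perms
        assert best is not None and best_order is not None and best_perms is not None

        # materialize the canonical form
        pos = {old: new for new, old in enumerate(best_order)}
        mols = tuple(self.mols[old] for old in best_order)
        states_out = []
        bonds_out = []
        for old in best_order:
            mdef = self.defs[self.mols[old]]
            perm = best_perms[old]
            st_items = []
            bd_items = []
            for site in mdef.site_names:
                src = perm.get(site, site)
                if src in self.states[old]:
                    st_items.append((site, self.states[old][src]))
                if src in self.bonds[old]:
                    j, sj = self.bonds[old][src]
                    # displayed partner site name under the partner's perm
                    pperm = best_perms[j]
                    inv = {v: k for k, v in pperm.items()}
                    bd_items.append((site, (pos[j], inv.get(sj, sj))))
            states_out.append(tuple(st_items))
            bonds_out.append(tuple(bd_items))
        return Species(
            mols=mols,
            states=tuple(states_out),
            bonds=tuple(bonds_out),
            compartment=self.compartment,
            label=best,
        )


def make_species(
    defs: Mapping[str, MoleculeDef],
    mols: Sequence[tuple[str, dict[str, str]]],
    bonds: Iterable[tuple[int, str, int, str]] = (),
    compartment: str = "CP",
) -> Species:
    """Convenience constructor: molecules as (name, states), explicit bonds."""
    g = _Graph(defs, compartment)
    for name, st in mols:
        mdef = defs[name]
        full = {}
        for sd in mdef.sites:
            if sd.states:
                full[sd.name] = st.get(sd.name, sd.states[0])
        extra = set(st) - set(full)
        if extra:
            raise StructuralError(f"unknown/stateless sites {extra} on {name}")
        g.add_molecule(name, full)
    for i, si, j, sj in bonds:
        g.add_bond(i, si, j, sj)
    return g.canonical()


def canonical_label(species: Species) -> str:
    """The canonical label (already carried by every :class:`Species`)."""
    return species.label


# ---------------------------------------------------------------------------
# patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternMol:
    """One molecule of a pattern.

    ``sites`` maps site name to ``(state, bond)`` where ``state`` is a
    concrete state or ``None`` (unspecified) and ``bond`` is FREE, BOUND,
    WILD or an integer bond id.  Sites not listed are fully unspecified.
    """

    name: str
    sites: tuple[tuple[str, tuple[str | None, object]], ...] = ()

    def site_map(self) -> dict[str, tuple[str | None, object]]:
        return dict(self.sites)


@dataclass(frozen=True)
class Pattern:
    """A site-graph pattern; ``compartment`` None means any compartment."""

    mols: tuple[PatternMol, ...]
    compartment: str | None = None

    def validate(self, defs: Mapping[str, MoleculeDef]) -> None:
        bond_ends: dict[object, int] = {}
        for pm in self.mols:
            if pm.name not in defs:
                raise RuleDefinitionError(f"unknown molecule {pm.name!r}")
            mdef = defs[pm.name]
            for site, (state, bond) in pm.sites:
                sdef = mdef.site(site)
                if state is not None and state not in sdef.states:
                    raise RuleDefinitionError(
                        f"state {state!r} not allowed on {pm.name}.{site}"
                    )
                if isinstance(bond, int):
                    bond_ends[bond] = bond_ends.get(bond, 0) + 1
        for b, cnt in bond_ends.items():
            if cnt != 2:
                raise RuleDefinitionError(f"bond id {b} has {cnt} endpoints")


@dataclass(frozen=True)
class Embedding:
    """An injective embedding of a pattern into a species.

    ``mol_map[p]`` is the species molecule index matched by pattern molecule
    ``p``; ``site_maps[p]`` maps pattern site names to species site names
    (non-identity only under site symmetry).
    """

    mol_map: tuple[int, ...]
    site_maps: tuple[tuple[tuple[str, str], ...], ...]

    def species_site(self, p: int, site: str) -> str:
        for a, b in self.site_maps[p]:
            if a == site:
                return b
        return site


def match(
    pattern: Pattern, species: Species, defs: Mapping[str, MoleculeDef]
) -> list[Embedding]:
    """Every injective, state- and bond-respecting embedding.

    Embeddings related by an automorphism of the pattern are distinct (the
    multiplicity convention used for mass-action rate assembly).
    """
    if pattern.compartment is not None and species.compartment != pattern.compartment:
        return []
    n = len(pattern.mols)
    out: list[Embedding] = []
    used: set[int] = set()
    mol_map: list[int] = [-1] * n
    site_maps: list[dict[str, str]] = [{}] * n

    def backtrack(p: int) -> None:
        if p == n:
            # verify pattern bonds (ids) connect matching species sites
            endpoints: dict[object, list[tuple[int, str]]] = {}
            for q, pm in enumerate(pattern.mols):
                for site, (_state, bond) in pm.sites:
                    if isinstance(bond, int):
                        endpoints.setdefault(bond, []).append(
                            (mol_map[q], site_maps[q].get(site, site))
                        )
            for ends in endpoints.values():
                (i, si), (j, sj) = ends
                if species.partner(i, si) != (j, sj):
                    return
            out.append(
                Embedding(
                    mol_map=tuple(mol_map),
                    site_maps=tuple(
                        tuple(sorted(site_maps[q].items())) for q in range(n)
                    ),
                )
            )
            return
        pm = pattern.mols[p]
        mdef = defs[pm.name]
        for i, name in enumerate(species.mols):
            if name != pm.name or i in used:
                continue
            for perm in mdef.site_permutations():
                ok = True
                for site, (state, bond) in pm.sites:
                    ssite = perm.get(site, site)
                    if state is not None and species.state_of(i, ssite) != state:
                        ok = False
                        break
                    partner = species.partner(i, ssite)
                    if bond is FREE or bond == FREE:
                        if partner is not None:
                            ok = False
                            break
                    elif bond is BOUND or bond == BOUND:
                        if partner is None:
                            ok = False
                            break
                    elif isinstance(bond, int):
                        if partner is None:
                            ok = False
                            break
                    # WILD: no constraint
                if ok:
                    used.add(i)
                    mol_map[p] = i
                    site_maps[p] = dict(perm)
                    backtrack(p + 1)
                    used.discard(i)
        return

    backtrack(0)
    # deduplicate identical (mol_map, effective site maps on constrained sites)
    seen = set()
    uniq = []
    for emb in out:
        key_parts = []
        for q, pm in enumerate(pattern.mols):
            eff = tuple(
                (site, emb.species_site(q, site)) for site, _ in pm.sites
            )
            key_parts.append((emb.mol_map[q], eff))
        key = tuple(key_parts)
        if key not in seen:
            seen.add(key)
            uniq.append(emb)
    return uniq


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Action:
    """One elementary transformation addressed by (pattern idx, mol idx, site)."""

    kind: str  # "bond-add" | "bond-delete" | "state-change" | "compartment-change"
    a: tuple[int, int, str] | None = None
    b: tuple[int, int, str] | None = None
    new_state: str | None = None
    new_compartment: str | None = None


@dataclass(frozen=True)
class Rule:
    """A unidirectional rule: reactant patterns, one action, a rate symbol.

    ``rate`` is an arithmetic expression over parameter symbols, evaluated at
    compile time.  Reversible model rules are represented as two Rule objects.
    """

    name: str
    reactants: tuple[Pattern, ...]
    action: Action
    rate: str

    @property
    def arity(self) -> int:
        return len(self.reactants)

    def validate(self, defs: Mapping[str, MoleculeDef]) -> None:
        for p in self.reactants:
            p.validate(defs)
        for ref in (self.action.a, self.action.b):
            if ref is None:
                continue
            ri, mi, site = ref
            if ri >= len(self.reactants) or mi >= len(self.reactants[ri].mols):
                raise RuleDefinitionError(f"rule {self.name}: bad action target {ref}")
            pm = self.reactants[ri].mols[mi]
            try:
                defs[pm.name].site(site)
            except KeyError as exc:
                raise RuleDefinitionError(
                    f"rule {self.name}: {pm.name} has no site {site!r}"
                ) from exc
        if self.action.kind == "bond-add" and len(self.reactants) != 2:
            raise RuleDefinitionError(
                f"rule {self.name}: intra-complex bond formation is not supported"
            )


_COMPARTMENT_VOLUME_RANK = {"EC": 0, "CP": 1, "PM": 2}


def merge_compartments(a: str, b: str) -> str | None:
    """Compartment of a complex formed by binding an ``a``- and a ``b``-complex.

    Co-localized partners keep their compartment; an extracellular species may
    bind a membrane species (receptor-ligand contact) yielding a PM complex;
    CP/PM and CP/EC contacts are forbidden (returns None -> rule inapplicable).
    """
    if a == b:
        return a
    pair = {a, b}
    if pair == {"EC", "PM"}:
        return "PM"
    return None


def _rehome(component: _Graph, defs: Mapping[str, MoleculeDef]) -> _Graph:
    """After fission, place a fragment in a compartment all its molecules allow.

    An extracellular molecule may remain part of a membrane complex (a
    receptor-bound ligand), so when the molecules' own compartment sets do
    not intersect, PM is admitted for EC-capable molecules.
    """
    allowed = None
    for name in component.mols:
        comps = defs[name].compartments
        allowed = comps if allowed is None else (allowed & comps)
    assert allowed is not None
    if not allowed:
        allowed = None
        for name in component.mols:
            comps = defs[name].compartments
            if "EC" in comps:
                comps = comps | {"PM"}
            allowed = comps if allowed is None else (allowed & comps)
        assert allowed is not None
    if component.compartment in allowed:
        return component
    if len(allowed) == 1:
        component.compartment = next(iter(allowed))
        return component
    raise StructuralError(
        f"ambiguous compartment for fragment {component.mols} "
        f"(allowed {sorted(allowed)})"
    )


def apply_rule(
    rule: Rule,
    reactants: Sequence[Species],
    defs: Mapping[str, MoleculeDef],
) -> list[tuple[tuple[Species, ...], int]]:
    """Apply ``rule`` to an *ordered* tuple of reactant species.

    Returns ``[(products, multiplicity), ...]`` where multiplicity counts the
    embedding combinations yielding the same product multiset.  The caller is
    responsible for order conventions and the A+A symmetry factor.
    """
    if len(reactants) != rule.arity:
        raise RuleDefinitionError(
            f"rule {rule.name} expects {rule.arity} reactants, got {len(reactants)}"
        )
    emb_lists = [
        match(p, sp, defs) for p, sp in zip(rule.reactants, reactants)
    ]
    if any(not e for e in emb_lists):
        return []

    # Multiplicity counts *distinct transformation events*: embeddings that
    # resolve the action to the same concrete target (the same bond, the same
    # site, the same translocating complex) are one event, so e.g. the two
    # automorphic embeddings into a symmetric dimer break one bond once,
    # while two symmetric state-change embeddings hit two different sites
    # and count twice.
    events: dict[tuple[str, ...], set] = {}
    product_cache: dict[tuple[str, ...], tuple[Species, ...]] = {}
    for combo in itertools.product(*emb_lists):
        g = _Graph.from_species(defs, reactants[0])
        offsets = [0]
        if rule.arity == 2:
            tgt = merge_compartments(
                reactants[0].compartment, reactants[1].compartment
            )
            if tgt is None:
                continue
            g2 = _Graph.from_species(defs, reactants[1])
            offsets.append(g.merge(g2))
            g.compartment = tgt

        def resolve(ref: tuple[int, int, str]) -> tuple[int, str]:
            ri, mi, site = ref
            emb = combo[ri]
            return offsets[ri] + emb.mol_map[mi], emb.species_site(mi, site)

        act = rule.action
        try:
            if act.kind == "bond-add":
                assert act.a and act.b
                i, si = resolve(act.a)
                j, sj = resolve(act.b)
                g.add_bond(i, si, j, sj)
                target: object = frozenset({(i, si), (j, sj)})
            elif act.kind == "bond-delete":
                assert act.a
                i, si = resolve(act.a)
                if si not in g.bonds[i]:
                    continue
                target = frozenset({(i, si), g.bonds[i][si]})
                g.del_bond(i, si)
            elif act.kind == "state-change":
                assert act.a and act.new_state is not None
                i, si = resolve(act.a)
                if si not in g.states[i]:
                    raise RuleDefinitionError(
                        f"rule {rule.name}: site {si} carries no state"
                    )
                g.states[i][si] = act.new_state
                target = (i, si)
            elif act.kind == "compartment-change":
                assert act.new_compartment is not None
                g.compartment = act.new_compartment
                target = act.new_compartment
            else:  # pragma: no cover
                raise RuleDefinitionError(f"unknown action kind {act.kind!r}")
        except StructuralError:
            continue

        comps = g.components()
        prods = []
        for comp in comps:
            frag = g.subgraph(comp, g.compartment)
            frag = _rehome(frag, defs)
            prods.append(frag.canonical())
        key = tuple(sorted(p.label for p in prods))
        product_cache.setdefault(key, tuple(prods))
        events.setdefault(key, set()).add(target)

    return [
        (product_cache[key], len(targets)) for key, targets in sorted(events.items())
    ]


def patterns_isomorphic(p1: Pattern, p2: Pattern, defs: Mapping[str, MoleculeDef]) -> bool:
    """Crude but sufficient pattern-isomorphism test (used for the A+A factor)."""

    def norm(p: Pattern):
        mols = []
        for pm in p.mols:
            mols.append((pm.name, tuple(sorted(pm.sites))))
        return (p.compartment, tuple(sorted(mols)))

    return norm(p1) == norm(p2)


# ---------------------------------------------------------------------------
# reaction network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """A concrete mass-action reaction.

    ``rate_expr`` is the rule's symbolic rate; the effective rate constant is
    ``eval(rate_expr) * multiplicity * sym_factor`` with an additional
    1/V(compartment) volume correction for bimolecular reactions, applied by
    the ODE compiler.
    """

    rule_id: str
    reactant_idx: tuple[int, ...]
    product_idx: tuple[int, ...]
    rate_expr: str
    multiplicity: int
    sym_factor: float  # 1.0 or 0.5 for A+A-type collisions
    bimolecular_compartment: str | None  # collision compartment, None if unimolecular


@dataclass
class ReactionNetwork:
    species: list[Species]
    reactions: list[Reaction]
    molecule_defs: dict[str, MoleculeDef]

    @property
    def index(self) -> dict[str, int]:
        return {sp.label: i for i, sp in enumerate(self.species)}

    def conservation_groups(self) -> dict[str, list[tuple[int, int]]]:
        """Per molecule name: list of (species index, copy number)."""
        groups: dict[str, list[tuple[int, int]]] = {
            name: [] for name in self.molecule_defs
        }
        for i, sp in enumerate(self.species):
            for name, cnt in sp.molecule_counts().items():
                groups[name].append((i, cnt))
        return groups

    def check_molecule_conservation(self) -> None:
        for rxn in self.reactions:
            lhs: Counter = Counter()
            rhs: Counter = Counter()
            for i in rxn.reactant_idx:
                lhs.update(self.species[i].molecule_counts())
            for i in rxn.product_idx:
                rhs.update(self.species[i].molecule_counts())
            if lhs != rhs:
                raise StructuralError(
                    f"reaction {rxn.rule_id} does not conserve molecules: "
                    f"{dict(lhs)} -> {dict(rhs)}"
                )

    def species_table(self) -> str:
        lines = ["index\tlabel\tcompartment"]
        for i, sp in enumerate(self.species):
            lines.append(f"{i}\t{sp.label}\t{sp.compartment}")
        return "\n".join(lines) + "\n"

    def reaction_table(self) -> str:
        lines = [
            "rule\treactants\tproducts\trate_expr\tmultiplicity\tsym_factor"
        ]
        for r in self.reactions:
            lines.append(
                "\t".join(
                    [
                        r.rule_id,
                        ",".join(map(str, r.reactant_idx)),
                        ",".join(map(str, r.product_idx)),
                        r.rate_expr,
                        str(r.multiplicity),
                        str(r.sym_factor),
                    ]
                )
            )
        return "\n".join(lines) + "\n"


def _collision_compartment(comps: Sequence[str]) -> str:
    """Effective collision compartment for a bimolecular encounter.

    A membrane-confined pair collides in the PM shell; a pair involving a
    bulk-phase partner (EC or CP) collides in that bulk volume.
    """
    best = comps[0]
    for c in comps[1:]:
        if _COMPARTMENT_VOLUME_RANK.get(c, 1) < _COMPARTMENT_VOLUME_RANK.get(best, 1):
            best = c
    return best


def generate_network(
    molecules: Mapping[str, MoleculeDef],
    rules: Sequence[Rule],
    seed_species: Sequence[Species],
    max_species: int = 10_000,
) -> ReactionNetwork:
    """Expand seed species to the rule-application fixpoint.

    Deterministic: breadth-first species discovery, products of each rule
    application enqueued in canonical-label order; species ordering is the
    discovery order.
    """
    for r in rules:
        r.validate(molecules)

    species: dict[str, Species] = {}
    order: list[Species] = []
    queue: deque[Species] = deque()

    def register(sp: Species, last_rule: str) -> None:
        if sp.label in species:
            return
        if len(species) >= max_species:
            raise NetworkExplosionError(max_species, last_rule)
        species[sp.label] = sp
        order.append(sp)
        queue.append(sp)

    for sp in seed_species:
        register(sp, "<seed>")

    reactions: dict[tuple, Reaction] = {}
    done_pairs: set[tuple] = set()

    uni_rules = [r for r in rules if r.arity == 1]
    bi_rules = [r for r in rules if r.arity == 2]
    sym_cache = {
        r.name: patterns_isomorphic(r.reactants[0], r.reactants[1], molecules)
        for r in bi_rules
    }

    def record(rule: Rule, rx: Sequence[Species], sym: float) -> None:
        for prods, mult in apply_rule(rule, rx, molecules):
            for p in prods:
                register(p, rule.name)
            ridx = tuple(sorted(species[s.label].label for s in rx))
            key = (
                rule.name,
                tuple(sorted(s.label for s in rx)),
                tuple(sorted(p.label for p in prods)),
            )
            if key in reactions:
                # same unordered reactants reached via both orders: fold in
                old = reactions[key]
                reactions[key] = Reaction(
                    rule_id=old.rule_id,
                    reactant_idx=old.reactant_idx,
                    product_idx=old.product_idx,
                    rate_expr=old.rate_expr,
                    multiplicity=old.multiplicity + mult,
                    sym_factor=old.sym_factor,
                    bimolecular_compartment=old.bimolecular_compartment,
                )
            else:
                idx = {lbl: i for i, lbl in enumerate(sp.label for sp in order)}
                reactions[key] = Reaction(
                    rule_id=rule.name,
                    reactant_idx=tuple(sorted(idx[s.label] for s in rx)),
                    product_idx=tuple(sorted(idx[p.label] for p in prods)),
                    rate_expr=rule.rate,
                    multiplicity=mult,
                    sym_factor=sym,
                    bimolecular_compartment=(
                        _collision_compartment([s.compartment for s in rx])
                        if len(rx) == 2
                        else None
                    ),
                )

    while queue:
        sp = queue.popleft()
        for rule in uni_rules:
            pairkey = (rule.name, sp.label)
            if pairkey in done_pairs:
                continue
            done_pairs.add(pairkey)
            record(rule, (sp,), 1.0)
        for rule in bi_rules:
            symmetric = sym_cache[rule.name]
            for other in list(order):
                pairkey = (rule.name, *sorted((sp.label, other.label)))
                if pairkey in done_pairs:
                    continue
                done_pairs.add(pairkey)
                sym = 0.5 if symmetric else 1.0
                record(rule, (sp, other), sym)
                if sp.label != other.label:
                    record(rule, (other, sp), sym)

    # reindex products/reactants against the final deterministic ordering
    idx = {sp.label: i for i, sp in enumerate(order)}
    final = []
    for key in sorted(reactions):
        r = reactions[key]
        rlabels, plabels = key[1], key[2]
        final.append(
            Reaction(
                rule_id=r.rule_id,
                reactant_idx=tuple(sorted(idx[l] for l in rlabels)),
                product_idx=tuple(sorted(idx[l] for l in plabels)),
                rate_expr=r.rate_expr,
                multiplicity=r.multiplicity,
                sym_factor=r.sym_factor,
                bimolecular_compartment=r.bimolecular_compartment,
            )
        )
    net = ReactionNetwork(
        species=order, reactions=final, molecule_defs=dict(molecules)
    )
    net.check_molecule_conservation()
    return net
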