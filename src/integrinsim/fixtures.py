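"""Tiny rule systems with exhaustively known answers.

Each fixture returns the model text in the BNGL subset plus an oracle dict:
the complete expected species and reaction lists (worked out by hand from
first principles — these systems are small enough to enumerate on paper) and,
where they exist, closed-form equilibrium values.  They make the engine and
the ODE compiler testable without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ToyFixture", "generate_toy_fixture", "FIXTURE_IDS"]

FIXTURE_IDS = ("dimer", "symmetric-dimer", "shuttling-pair", "kinase-cascade")


@dataclass
class ToyFixture:
    fixture_id: str
    model_text: str
    species: set[str]          # expected canonical labels
    n_reactions: int
    oracle: dict               # closed forms / conventions, fixture-specific

    def write(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / f"{self.fixture_id}.bngl").write_text(self.model_text)
        lines = ["label"] + sorted(self.species)
        (d / f"{self.fixture_id}.species.txt").write_text("\n".join(lines) + "\n")


_DIMER = """
begin parameters
  kon 0.2
  koff 0.1
  A_tot 2.0
  B_tot 3.0
end parameters
begin compartments
  CP 1.0
end compartments
begin molecule types
  A(b) @CP
  B(a) @CP
end molecule types
begin seed species
  A(b)@CP  A_tot
  B(a)@CP  B_tot
end seed species
begin observables
  AB  A(b!+)
end observables
begin reaction rules
  B1: A(b) + B(a) <-> A(b!1).B(a!1)  kon, koff
end reaction rules
"""


def _dimer_equilibrium(kon: float, koff: float, a0: float, b0: float) -> float:
    """[AB] at equilibrium: root of the quadratic KD relation."""
    kd = koff / kon
    s = a0 + b0 + kd
    return (s - math.sqrt(s * s - 4 * a0 * b0)) / 2.0


_SYM_DIMER = """
begin parameters
  kon 0.2
  koff 0.1
  A_tot 2.0
end parameters
begin compartments
  CP 1.0
end compartments
begin molecule types
  A(b) @CP
end molecule types
begin seed species
  A(b)@CP  A_tot
end seed species
begin observables
  AA  A(b!1).A(b!1)
end observables
begin reaction rules
  S1: A(b) + A(b) <-> A(b!1).A(b!1)  kon, koff
end reaction rules
"""


def _sym_dimer_equilibrium(kon: float, koff: float, a0: float) -> float:
    """[AA] at equilibrium under the kon/2 forward convention.

    d[AA]/dt = (kon/2)[A]^2 - koff[AA] = 0 with [A] + 2[AA] = a0,
    so [AA] = [A]^2/kd with kd = 2 koff/kon and
    2[A]^2 + kd [A] - kd a0 = 0.
    """
    kd = 2.0 * koff / kon
    a = (-kd + math.sqrt(kd * kd + 8.0 * kd * a0)) / 4.0
    return (a0 - a) / 2.0


_SHUTTLE = """
begin parameters
  kin 0.02
  kout 0.01
  KD 0.5
  koff 0.1
  M_tot 1.0
  N_tot 2.0
end parameters
begin compartments
  PM 0.01
  CP 1.0
end compartments
begin molecule types
  M(x) @CP,PM
  N(x) @PM
end molecule types
begin seed species
  M(x)@CP  M_tot
  N(x)@PM  N_tot
end seed species
begin observables
  M_PM  M()@PM
  MN    M(x!+)
end observables
begin reaction rules
  T1: M(x)@CP <-> M(x)@PM  kin, kout
  B1: M(x)@PM + N(x) <-> M(x!1).N(x!1)  koff/KD, koff
end reaction rules
"""


def _shuttle_equilibrium(
    kin: float, kout: float, kd: float, m0: float, n0: float, v_pm: float
) -> dict:
    """Amount-based equilibrium of shuttle + membrane binding.

    Free pools: M_cp*kin = M_pm*kout and the PM binding satisfies
    MN = M_pm*N_free/(KD*V_pm) (the membrane confinement scales the
    bimolecular encounter by 1/V_pm, so the effective amount-scale KD is
    KD*V_pm).  Solved exactly via the resulting quadratic.
    """
    r = kin / kout                    # M_pm / M_cp at equilibrium
    kde = kd * v_pm                   # effective KD on the amount scale
    # unknown f = free membrane M;  total M: f*(1+1/r) + MN = m0
    # MN = f*(n0 - MN)/kde  ->  MN = f*n0/(kde + f)
    # solve f*(1+1/r) + f*n0/(kde+f) = m0 by the quadratic in f
    c1 = 1.0 + 1.0 / r
    # c1*f^2 + (c1*kde + n0 - m0)*f - m0*kde = 0
    b = c1 * kde + n0 - m0
    f = (-b + math.sqrt(b * b + 4.0 * c1 * m0 * kde)) / (2.0 * c1)
    mn = f * n0 / (kde + f)
    return {"M_pm_free": f, "M_cp_free": f / r, "MN": mn, "M_PM": f + mn}


_CASCADE = """
begin parameters
  kon 1.0
  koff 0.1
  kcat 0.5
  kdeph 0.05
  E_tot 0.5
  S_tot 2.0
end parameters
begin compartments
  CP 1.0
end compartments
begin molecule types
  E(s) @CP
  S(e,p~U~P) @CP
end molecule types
begin seed species
  E(s)@CP      E_tot
  S(e,p~U)@CP  S_tot
end seed species
begin observables
  SP  S(p~P)
end observables
begin reaction rules
  C1: E(s) + S(e,p~U) <-> E(s!1).S(e!1,p~U)  kon, koff
  C2: E(s!1).S(e!1,p~U) -> E(s!1).S(e!1,p~P)  kcat
  C2b: E(s!1).S(e!1,p~P) -> E(s) + S(e,p~P)  koff
  C3: S(e,p~P) -> S(e,p~U)  kdeph
end reaction rules
"""


def generate_toy_fixture(fixture_id: str) -> ToyFixture:
    if fixture_id == "dimer":
        return ToyFixture(
            fixture_id=fixture_id,
            model_text=_DIMER,
            species={"@CP:A(b)", "@CP:B(a)", "@CP:A(b!1).B(a!1)"},
            n_reactions=2,
            oracle={"equilibrium_AB": _dimer_equilibrium},
        )
    if fixture_id == "symmetric-dimer":
        return ToyFixture(
            fixture_id=fixture_id,
            model_text=_SYM_DIMER,
            species={"@CP:A(b)", "@CP:A(b!1).A(b!1)"},
            n_reactions=2,
            oracle={
                "equilibrium_AA": _sym_dimer_equilibrium,
                "forward_sym_factor": 0.5,
                "reverse_multiplicity": 2,
            },
        )
    if fixture_id == "shuttling-pair":
        return ToyFixture(
            fixture_id=fixture_id,
            model_text=_SHUTTLE,
            species={
                "@CP:M(x)",
                "@PM:M(x)",
                "@PM:N(x)",
                "@PM:M(x!1).N(x!1)",
            },
            n_reactions=4,
            oracle={"equilibrium": _shuttle_equilibrium},
        )
    if fixture_id == "kinase-cascade":
        return ToyFixture(
            fixture_id=fixture_id,
            model_text=_CASCADE,
            species={
                "@CP:E(s)",
                "@CP:S(e,p~U)",
                "@CP:S(e,p~P)",
                "@CP:E(s!1).S(e!1,p~U)",
                "@CP:E(s!1).S(e!1,p~P)",
            },
            # C1 forward + reverse (U-complex), C2, C2b release, C3 on the
            # free phospho-substrate (its e site must be free): 5 exactly.
            n_reactions=5,
            oracle={},
        )
    raise KeyError(f"unknown fixture id {fixture_id!r}")
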