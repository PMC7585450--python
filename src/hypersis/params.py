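"""Epidemic parameters for SIS contagion on hypergraphs."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["EpidemicParams", "RULES", "WIRINGS", "SIGNS"]

RULES = ("collective", "individual")
WIRINGS = ("correlated", "uncorrelated")
SIGNS = ("contagion", "healing")


@dataclass(frozen=True)
class EpidemicParams:
    """Rates and structural options of the contagion model.

    Parameters
    ----------
    gamma : float
        Healing rate of infected nodes (1/time), > 0.
    beta2 : float
        Infection rate per link with an infected partner (1/time).
    beta3 : float
        Triangle rate (1/time).  Under ``rule="collective"`` a susceptible
        member is infected at this rate when both other members are infected;
        under ``rule="individual"``, when at least one is.  With
        ``triangle_sign="healing"`` triangles recover infected members at
        this rate instead (same condition on the other members).
    wiring : str
        "correlated" (triangle membership ∝ product of link degrees) or
        "uncorrelated" (uniform).
    beta_m : dict, optional
        Rates per hyperedge size for the all-sizes model, e.g. {2: .., 4: ..}.
    mean_km : dict, optional
        Mean size-m hyperdegree ``<k^(m)>`` per size for the all-sizes model.
    """

    gamma: float
    beta2: float = 0.0
    beta3: float = 0.0
    rule: str = "collective"
    wiring: str = "correlated"
    triangle_sign: str = "contagion"
    beta_m: dict | None = None
    mean_km: dict | None = None

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if self.beta2 < 0 or self.beta3 < 0:
            raise ValueError("rates must be non-negative")
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}")
        if self.wiring not in WIRINGS:
            raise ValueError(f"wiring must be one of {WIRINGS}")
        if self.triangle_sign not in SIGNS:
            raise ValueError(f"triangle_sign must be one of {SIGNS}")
        if self.beta_m is not None and any(v < 0 for v in self.beta_m.values()):
            raise ValueError("beta_m rates must be non-negative")

    @property
    def sign(self) -> int:
        """+1 for triangle contagion, -1 for higher-order healing."""
        return 1 if self.triangle_sign == "contagion" else -1

    def with_(self, **kwargs) -> "EpidemicParams":
        return replace(self, **kwargs)
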