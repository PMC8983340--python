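"""Run configuration: thresholds, route-suitability map, manual overrides.

Defaults reproduce the packaged worked examples without any override.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, field_validator

from .annotations import OrganSystem, Route

__all__ = ["RunConfig", "DEFAULT_ROUTE_SUITABILITY"]

#: Which administration routes deliver a drug to each infected organ system.
#: Only a few cells are fixed by clinical common sense (inhalation for
#: respiratory infections, intravenous for cardiovascular ones); the rest are
#: declared defaults, fully overridable via :attr:`RunConfig.route_suitability`.
DEFAULT_ROUTE_SUITABILITY: dict[OrganSystem, frozenset[Route]] = {
    OrganSystem.RESPIRATORY: frozenset({Route.INHALATION, Route.ORAL}),
    OrganSystem.DIGESTIVE: frozenset({Route.ORAL}),
    OrganSystem.CARDIOVASCULAR: frozenset({Route.INTRAVENOUS}),
    OrganSystem.NERVOUS: frozenset({Route.INTRAVENOUS, Route.ORAL}),
    OrganSystem.INTEGUMENTARY: frozenset({Route.TOPICAL, Route.ORAL}),
    OrganSystem.UROGENITAL: frozenset({Route.ORAL, Route.INTRAVENOUS}),
    OrganSystem.MULTIPLE: frozenset({Route.ORAL, Route.INTRAVENOUS}),
}


class RunConfig(BaseModel):
    """Tunable parameters for scoring, clustering and gap prediction.

    ``overrides`` maps provenance-recorded keys to manual values:

    - ``"bsa:<drug_id>:<virus_id>:<component>"`` replaces a BSA component
      (component in ``c_sar, c_dds, c_tr, c_ic, c_roa, c_phyl``);
    - ``"bcc:<drug_1>+<drug_2>:<virus_id>:<coefficient>"`` replaces a
      combination coefficient (``k_di, k_dti, k_drs, k_roa``); the drug pair
      is canonical (lexicographic).
    """

    similarity_threshold: float = Field(default=0.4, gt=0.0, le=1.0)
    cluster_cutoff: float = Field(default=0.6, ge=0.0, le=1.0)
    effectiveness_delta: float = Field(default=5.0, gt=0.0)
    route_suitability: dict[OrganSystem, frozenset[Route]] = Field(
        default_factory=lambda: dict(DEFAULT_ROUTE_SUITABILITY)
    )
    overrides: dict[str, float] = Field(default_factory=dict)
    seed: int = 0
    log_level: str = "WARNING"

    @field_validator("route_suitability")
    @classmethod
    def _non_empty_route_sets(cls, v):
        for system, routes in v.items():
            if not routes:
                raise ValueError(f"route_suitability[{system}] must be non-empty")
        return v

    def suitable_routes(self, systems) -> frozenset[Route]:
        """Union of suitable routes over the given infected organ systems."""
        out: set[Route] = set()
        for system in systems:
            out |= self.route_suitability.get(OrganSystem(system), frozenset())
        return frozenset(out)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a JSON config file, merging over the defaults."""
        data = json.loads(Path(path).read_text())
        return cls.model_validate(data)

    model_config = {"frozen": False}
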