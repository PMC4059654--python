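"""Model family topologies.

Seven nested steady-state models of ATP production and consumption in a
permeabilized cardiomyocyte suspension.  All models share three well-mixed
compartments — the measurement SOLUTION, the CYTOSOL and the mitochondrial
intermembrane space (IMS) — linked by linear exchange (flux = coefficient
times concentration difference).  The richer models add a phenomenological
fourth compartment C4 that houses ATPases tightly coupled to endogenous
pyruvate kinase (PK):

=====  ===========================================================
model  structure
=====  ===========================================================
1      ATP synthase in IMS, one ATPase in cytosol; no endogenous PK
2s     model 1 + endogenous PK in the cytosol
2      model 2s with the cytosolic ATPase split in two, each part
       with its own apparent (Km_ATP, Km_ADP) pair
3s     model 2s + compartment C4 (attached to the cytosol) hosting a
       second ATPase and a second endogenous PK; apparent affinities
       shared with the cytosolic reactions
3      model 3s with a separate (Km_ATP, Km_ADP) pair for the C4 ATPase
4s/4   as 3s/3 but with C4 attached to the solution instead of the
       cytosol
=====  ===========================================================

Models 1 ⊂ 2s ⊂ 2, 2s ⊂ 3s ⊂ 3, 2s ⊂ 4s ⊂ 4 and 2 ⊂ 3, 2 ⊂ 4 are nested;
3 and 4 (and 3s and 4s) are not nested with each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SOLUTION = "solution"
CYTOSOL = "cytosol"
IMS = "ims"
C4 = "c4"

# reactions
ATP_SYNTHASE = "atp_synthase"
ATPASE1 = "atpase1"
ATPASE2 = "atpase2"
PKEND1 = "pkend1"
PKEND2 = "pkend2"
PKEXO = "pkexo"

MODEL_IDS = ("1", "2s", "2", "3s", "3", "4s", "4")

#: free kinetic parameters per model (order used for fitting vectors)
FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "1": ("V_syn", "C_sol_cyt", "C_cyt_ims", "V_atpase1", "Km_atp1", "Km_adp1"),
    "2s": ("V_syn", "C_sol_cyt", "C_cyt_ims", "V_atpase1", "Km_atp1", "Km_adp1",
           "V_pkend1", "Km_pk_adp"),
    "2": ("V_syn", "C_sol_cyt", "C_cyt_ims", "V_atpase1", "Km_atp1", "Km_adp1",
          "V_atpase2", "Km_atp2", "Km_adp2", "V_pkend1", "Km_pk_adp"),
    "3s": ("V_syn", "C_sol_cyt", "C_cyt_ims", "C_c4", "V_atpase1", "Km_atp1",
           "Km_adp1", "V_atpase2", "V_pkend1", "Km_pk_adp", "V_pkend2"),
    "3": ("V_syn", "C_sol_cyt", "C_cyt_ims", "C_c4", "V_atpase1", "Km_atp1",
          "Km_adp1", "V_atpase2", "Km_atp2", "Km_adp2", "V_pkend1", "Km_pk_adp",
          "V_pkend2"),
    "4s": ("V_syn", "C_sol_cyt", "C_cyt_ims", "C_c4", "V_atpase1", "Km_atp1",
           "Km_adp1", "V_atpase2", "V_pkend1", "Km_pk_adp", "V_pkend2"),
    "4": ("V_syn", "C_sol_cyt", "C_cyt_ims", "C_c4", "V_atpase1", "Km_atp1",
          "Km_adp1", "V_atpase2", "Km_atp2", "Km_adp2", "V_pkend1", "Km_pk_adp",
          "V_pkend2"),
}

#: nested (simple, complex) pairs eligible for extra-sum-of-squares F-tests
NESTED_PAIRS: tuple[tuple[str, str], ...] = (
    ("1", "2s"), ("1", "2"), ("1", "3s"), ("1", "3"), ("1", "4s"), ("1", "4"),
    ("2s", "2"), ("2s", "3s"), ("2s", "3"), ("2s", "4s"), ("2s", "4"),
    ("2", "3"), ("2", "4"), ("3s", "3"), ("4s", "4"),
)


class TopologyError(ValueError):
    """Reaction placed in a compartment the topology does not contain."""


@dataclass(frozen=True)
class ModelTopology:
    """Compartments, reaction placements and exchanges of one model variant."""

    model_id: str
    compartments: tuple[str, ...]
    #: reaction name -> hosting compartment
    reactions: dict[str, str] = field(hash=False)
    #: (comp_a, comp_b) -> name of the exchange coefficient parameter
    exchanges: dict[tuple[str, str], str] = field(hash=False)
    shared_affinities: bool = False

    def __post_init__(self) -> None:
        for rxn, comp in self.reactions.items():
            if comp not in self.compartments:
                raise TopologyError(
                    f"model {self.model_id}: reaction {rxn} placed in missing "
                    f"compartment {comp}")
        # every non-solution compartment must be reachable through exchanges
        seen = {SOLUTION}
        frontier = [SOLUTION]
        while frontier:
            here = frontier.pop()
            for a, b in self.exchanges:
                for other, this in ((a, b), (b, a)):
                    if this == here and other not in seen:
                        seen.add(other)
                        frontier.append(other)
        missing = set(self.compartments) - seen
        if missing:
            raise TopologyError(
                f"model {self.model_id}: compartments {sorted(missing)} are "
                "not connected to the exchange graph")

    @property
    def free_parameters(self) -> tuple[str, ...]:
        return FREE_PARAMS[self.model_id]

    @property
    def k(self) -> int:
        """Number of free kinetic parameters."""
        return len(FREE_PARAMS[self.model_id])

    @property
    def has_c4(self) -> bool:
        return C4 in self.compartments

    def affinity_names(self, reaction: str) -> tuple[str, ...]:
        """Names of the (Km, Ki) parameters governing *reaction*."""
        if reaction == ATPASE1:
            return ("Km_atp1", "Km_adp1")
        if reaction == ATPASE2:
            if self.shared_affinities:
                return ("Km_atp1", "Km_adp1")
            return ("Km_atp2", "Km_adp2")
        if reaction in (PKEND1, PKEND2):
            return ("Km_pk_adp",)
        raise KeyError(reaction)


def topology(model_id: str) -> ModelTopology:
    """Build the :class:`ModelTopology` for one of the seven model ids."""
    mid = str(model_id)
    if mid not in MODEL_IDS:
        raise KeyError(f"unknown model id {model_id!r}; valid ids: {MODEL_IDS}")
    compartments = [SOLUTION, CYTOSOL, IMS]
    reactions = {ATP_SYNTHASE: IMS, ATPASE1: CYTOSOL, PKEXO: SOLUTION}
    exchanges = {(SOLUTION, CYTOSOL): "C_sol_cyt", (CYTOSOL, IMS): "C_cyt_ims"}
    if mid != "1":
        reactions[PKEND1] = CYTOSOL
    if mid == "2":
        reactions[ATPASE2] = CYTOSOL
    if mid in ("3s", "3", "4s", "4"):
        compartments.append(C4)
        reactions[ATPASE2] = C4
        reactions[PKEND2] = C4
        anchor = CYTOSOL if mid in ("3s", "3") else SOLUTION
        exchanges[(anchor, C4)] = "C_c4"
    return ModelTopology(
        model_id=mid,
        compartments=tuple(compartments),
        reactions=reactions,
        exchanges=exchanges,
        shared_affinities=mid.endswith("s"),
    )
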