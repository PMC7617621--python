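"""Exception hierarchy.

All user-facing errors derive from :class:`HetwalkError`; specification and
validation problems are also ``ValueError`` s, numerical failures are
``RuntimeError`` s, so generic handling keeps working.
"""


class HetwalkError(Exception):
    """Base class for all hetwalk errors."""


class SpecificationError(HetwalkError, ValueError):
    """Invalid lattice / scenario specification (bad N, q, boundary, tiling...)."""


class GeometryError(SpecificationError):
    """Sites do not have the adjacency a builder requires (e.g. barrier between
    non-neighbors, long-range connection between neighbors)."""


class DefectValidationError(HetwalkError, ValueError):
    """A heterogeneity set violates the positivity constraints on the perturbed
    transition probabilities."""


class DomainError(HetwalkError, ValueError):
    """Evaluation point outside the admissible region (e.g. |z| beyond the
    convergence radius of a generating function)."""


class NumericalError(HetwalkError, RuntimeError):
    """A numerical procedure failed (singular defect matrix, non-negligible
    imaginary residue in a series inversion, ...)."""
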