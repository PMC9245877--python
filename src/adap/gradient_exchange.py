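"""One-shot communication layer.

A collaborating site evaluates its gradient (and, for the second-order
variant, its Hessian) of the local average loss at a broadcast anchor
``beta_bar`` and ships only those summaries to the lead site.  The lead site
aggregates them into the surrogate objective

    Ltilde1(beta) = L1(beta) + c' beta
    Ltilde2(beta) = Ltilde1(beta) + (1/2) (beta - beta_bar)' D (beta - beta_bar)

with c = grad L(beta_bar) - grad L1(beta_bar) and
D = hess L(beta_bar) - hess L1(beta_bar), where L is the sample-size-weighted
pooled loss over all K sites.  By construction the surrogate's gradient at the
anchor equals the pooled gradient (and, for order 2, its Hessian equals the
pooled Hessian), which is what makes the one-shot correction work.

No individual-level rows ever leave a site: a GradientPacket carries exactly
(site_id, n_k, anchor_hash, grad1[, grad2]).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    SiteDataset,
    as_beta,
    logistic_gradient,
    logistic_hessian,
    logistic_loss,
)

__all__ = [
    "GradientPacket",
    "SurrogateObjective",
    "CommLedger",
    "anchor_hash",
    "make_packet",
    "build_surrogate",
    "surrogate_value",
    "surrogate_gradient",
    "comm_cost",
    "write_packet",
    "read_packet",
]


def anchor_hash(beta_bar) -> str:
    """Checksum identifying the broadcast anchor a packet was evaluated at."""
    b = np.ascontiguousarray(as_beta(beta_bar))
    return hashlib.sha256(b.tobytes()).hexdigest()[:16]


@dataclass
class GradientPacket:
    """Summary statistics one collaborating site transmits."""

    site_id: str
    n_k: int
    grad1: np.ndarray
    grad2: np.ndarray | None = None
    anchor: str = ""

    def __post_init__(self) -> None:
        self.grad1 = np.asarray(self.grad1, dtype=float).ravel()
        if self.grad2 is not None:
            self.grad2 = np.asarray(self.grad2, dtype=float)
            if self.grad2.shape != (self.grad1.size, self.grad1.size):
                raise ValueError(
                    f"grad2 shape {self.grad2.shape} does not match p={self.grad1.size}"
                )
            if not np.allclose(self.grad2, self.grad2.T, atol=1e-10):
                raise ValueError("grad2 must be symmetric")


@dataclass
class SurrogateObjective:
    """The lead-site surrogate loss (order 1 or 2), anchored at beta_bar."""

    lead: SiteDataset
    beta_bar: np.ndarray
    c: np.ndarray
    D: np.ndarray | None
    order: int
    N: int
    K: int

    def __post_init__(self) -> None:
        self.beta_bar = np.asarray(self.beta_bar, dtype=float).ravel()
        self.c = np.asarray(self.c, dtype=float).ravel()
        if self.order not in (1, 2):
            raise ValueError(f"order must be 1 or 2, got {self.order}")
        if self.order == 2 and self.D is None:
            raise ValueError("order=2 surrogate requires D")
        if self.order == 1:
            self.D = None

    def with_lead(self, lead: SiteDataset, c: np.ndarray) -> "SurrogateObjective":
        """Same remote aggregates, different lead data / correction (CV folds)."""
        return SurrogateObjective(lead, self.beta_bar, c, self.D, self.order, self.N, self.K)


@dataclass
class CommLedger:
    """Exact accounting of scalars moved between sites."""

    scalars_sent_per_site: dict = field(default_factory=dict)
    broadcast_scalars: int = 0
    dense_grad2: bool = False

    @property
    def total(self) -> int:
        return int(sum(self.scalars_sent_per_site.values()))


def make_packet(ds: SiteDataset, beta_bar, order: int = 1) -> GradientPacket:
    """What a collaborating site computes and sends for one broadcast."""
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    if ds.n_k == 0:
        raise ValueError("cannot build a packet from an empty site")
    g1 = logistic_gradient(ds, beta_bar)
    g2 = logistic_hessian(ds, beta_bar) if order == 2 else None
    return GradientPacket(ds.site_id, ds.n_k, g1, g2, anchor=anchor_hash(beta_bar))


def build_surrogate(
    lead: SiteDataset,
    packets: list[GradientPacket],
    beta_bar,
    order: int = 1,
) -> SurrogateObjective:
    """Aggregate remote packets with the lead's own gradients into Ltilde."""
    bbar = as_beta(beta_bar)
    h = anchor_hash(bbar)
    for pk in packets:
        if pk.anchor and pk.anchor != h:
            raise ValueError(
                f"stale packet from {pk.site_id}: anchor {pk.anchor} != broadcast {h}"
            )
        if order == 2 and pk.grad2 is None:
            raise ValueError(f"packet from {pk.site_id} lacks grad2 but order=2 requested")

    p = lead.p
    N = lead.n_k + sum(pk.n_k for pk in packets)
    if not packets:  # single-site study: the corrections are exactly zero
        D = np.zeros((p, p)) if order == 2 else None
        return SurrogateObjective(lead, bbar, np.zeros(p), D, order, int(N), 1)

    g_lead = logistic_gradient(lead, bbar)
    g_pool = lead.n_k * g_lead
    for pk in packets:
        g_pool = g_pool + pk.n_k * pk.grad1
    g_pool /= N
    c = g_pool - g_lead

    D = None
    if order == 2:
        H_lead = logistic_hessian(lead, bbar)
        H_pool = lead.n_k * H_lead
        for pk in packets:
            H_pool = H_pool + pk.n_k * pk.grad2
        H_pool /= N
        D = H_pool - H_lead
        D = 0.5 * (D + D.T)

    return SurrogateObjective(lead, bbar, c, D, order, int(N), len(packets) + 1)


def surrogate_value(s: SurrogateObjective, beta) -> float:
    b = as_beta(beta)
    val = logistic_loss(s.lead, b) + float(s.c @ b)
    if s.order == 2:
        d = b - s.beta_bar
        val += 0.5 * float(d @ s.D @ d)
    return val


def surrogate_gradient(s: SurrogateObjective, beta) -> np.ndarray:
    b = as_beta(beta)
    g = logistic_gradient(s.lead, b) + s.c
    if s.order == 2:
        g = g + s.D @ (b - s.beta_bar)
    return g


def comm_cost(K: int, p: int, order: int = 1, *, count_n: bool = True,
              dense_grad2: bool = False) -> CommLedger:
    """Scalars transferred in one protocol round.

    Each of the K-1 collaborating sites sends p gradient entries (order 1)
    plus, for order 2, the p(p+1)/2 distinct entries of its symmetric Hessian
    (or p^2 with ``dense_grad2=True``, the looser dense-matrix accounting),
    plus one scalar for n_k when ``count_n``.  The lead broadcasts the
    p-vector anchor to each collaborating site.
    """
    if K < 1 or p < 1:
        raise ValueError("K and p must be positive")
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    per_site = p + (int(count_n))
    if order == 2:
        per_site += p * p if dense_grad2 else p * (p + 1) // 2
    ledger = CommLedger(dense_grad2=dense_grad2)
    ledger.scalars_sent_per_site = {f"site_{k}": per_site for k in range(2, K + 1)}
    ledger.broadcast_scalars = p * (K - 1)
    return ledger


# --- flat-text packet serialization (interoperable with non-Python agents) ---

def write_packet(pk: GradientPacket, path) -> None:
    """Serialize a packet to a flat key=value text file.

    grad2 is stored as the row-major upper triangle of the symmetric matrix.
    The file contains exactly the declared summary fields -- never data rows.
    """
    lines = [
        f"site_id={pk.site_id}",
        f"n_k={pk.n_k}",
        f"anchor_hash={pk.anchor}",
        "grad1=" + ",".join(repr(float(v)) for v in pk.grad1),
    ]
    if pk.grad2 is not None:
        iu = np.triu_indices(pk.grad1.size)
        lines.append("grad2_upper="
                     + ",".join(repr(float(v)) for v in pk.grad2[iu]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_packet(path) -> GradientPacket:
    fields: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                key, _, val = line.partition("=")
                fields[key] = val
    g1 = np.array([float(v) for v in fields["grad1"].split(",")])
    g2 = None
    if "grad2_upper" in fields:
        p = g1.size
        g2 = np.zeros((p, p))
        iu = np.triu_indices(p)
        g2[iu] = [float(v) for v in fields["grad2_upper"].split(",")]
        g2 = g2 + np.triu(g2, 1).T
    return GradientPacket(
        fields["site_id"], int(fields["n_k"]), g1, g2, anchor=fields.get("anchor_hash", "")
    )
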