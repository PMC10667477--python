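"""Episode segmentation and buy/cart/no-buy tagging.

Each product-page view becomes one episode whose *decision time* is the
moment the page was left. Two tagging schemes are supported:

* two-class: any product that was ever carted or bought makes every one
  of its views a ``buy`` episode; everything else is ``no_buy``.
* three-class: backward labeling by the product's eventual fate — views
  up to and including the cart action are ``cart``, later views (after a
  cart that leads to a purchase, or all views of a product bought
  without carting) are ``buy``; untouched products are ``no_buy``.
  A product viewed six times, carted at view 3 and bought at view 5 is
  tagged [cart, cart, cart, buy, buy, buy].
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import ValidationError, validate_events

__all__ = [
    "Episode",
    "LabeledEpisode",
    "segment_episodes",
    "label_two_class",
    "label_three_class",
    "labels_to_frame",
    "coarsen_to_two_class",
]

SCHEMES = ("two_class", "three_class")
LABELS = ("buy", "cart", "no_buy")


@dataclass(frozen=True)
class Episode:
    subject_id: str
    product_id: str
    view_index: int
    start_time: float
    decision_time: float  # page-leave time t

    def __post_init__(self):
        if not self.decision_time > self.start_time:
            raise ValueError("decision_time must exceed start_time")

    @property
    def duration(self) -> float:
        return self.decision_time - self.start_time

    @property
    def episode_id(self) -> str:
        return f"{self.subject_id}/{self.product_id}/{self.view_index}"


@dataclass(frozen=True)
class LabeledEpisode:
    episode: Episode
    scheme: str
    label: str

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.scheme == "two_class" and self.label == "cart":
            raise ValueError("two_class scheme has no cart label")


def segment_episodes(events: pd.DataFrame) -> list[Episode]:
    """One episode per event row; decision time = page-leave time."""
    events = validate_events(events)
    return [
        Episode(
            subject_id=str(row.subject_id),
            product_id=str(row.product_id),
            view_index=int(row.view_index),
            start_time=float(row.enter_time),
            decision_time=float(row.leave_time),
        )
        for row in events.itertuples(index=False)
    ]


def _product_actions(events: pd.DataFrame):
    """Per (subject, product): view_index of cart and of buy (or None)."""
    actions: dict[tuple[str, str], dict[str, int | None]] = {}
    for row in events.itertuples(index=False):
        key = (str(row.subject_id), str(row.product_id))
        entry = actions.setdefault(key, {"cart": None, "buy": None})
        if row.action in ("cart", "buy"):
            entry[row.action] = int(row.view_index)
    return actions


def label_two_class(episodes: list[Episode], events: pd.DataFrame) -> list[LabeledEpisode]:
    """Every view of a product with any cart or buy action is ``buy``."""
    events = validate_events(events)
    actions = _product_actions(events)
    out = []
    for ep in episodes:
        entry = actions.get((ep.subject_id, ep.product_id), {"cart": None, "buy": None})
        label = "buy" if (entry["cart"] is not None or entry["buy"] is not None) else "no_buy"
        out.append(LabeledEpisode(ep, "two_class", label))
    return out


def label_three_class(episodes: list[Episode], events: pd.DataFrame) -> list[LabeledEpisode]:
    """Backward labeling by product fate (see module docstring)."""
    events = validate_events(events)
    actions = _product_actions(events)
    out = []
    for ep in episodes:
        entry = actions.get((ep.subject_id, ep.product_id), {"cart": None, "buy": None})
        cart_view, buy_view = entry["cart"], entry["buy"]
        if cart_view is None and buy_view is None:
            label = "no_buy"
        elif buy_view is None:
            label = "cart"  # carted, never bought: all views cart
        elif cart_view is None:
            label = "buy"  # bought without carting: all views buy
        else:
            if cart_view >= buy_view:
                raise ValidationError(
                    f"product {ep.product_id}: buy at view {buy_view} does not follow "
                    f"cart at view {cart_view}"
                )
            label = "cart" if ep.view_index <= cart_view else "buy"
        out.append(LabeledEpisode(ep, "three_class", label))
    return out


def coarsen_to_two_class(labeled: list[LabeledEpisode]) -> list[LabeledEpisode]:
    """Map three-class labels {cart, buy} -> buy; reproduces two-class tagging."""
    out = []
    for le in labeled:
        label = "buy" if le.label in ("cart", "buy") else "no_buy"
        out.append(LabeledEpisode(le.episode, "two_class", label))
    return out


def labels_to_frame(labeled: list[LabeledEpisode]) -> pd.DataFrame:
    """Serialize labeled episodes to the flat CSV layout."""
    return pd.DataFrame(
        {
            "subject_id": [le.episode.subject_id for le in labeled],
            "product_id": [le.episode.product_id for le in labeled],
            "view_index": [le.episode.view_index for le in labeled],
            "start_time": [le.episode.start_time for le in labeled],
            "decision_time": [le.episode.decision_time for le in labeled],
            "scheme": [le.scheme for le in labeled],
            "label": [le.label for le in labeled],
        }
    )
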