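"""Versioned JSON serialization and rule rendering for both model families.

Schema ``petasym-model/1``: a ``kind`` tag ("c45" or "lmt"), the class
labels, and a nested model body.  Feature names are validated against
the canonical region list (or an explicit feature set) at parse time so
a model referencing an unknown region fails loudly.  ``render_rules``
prints models in the printed-rule style ``AI[region] ≤ t: class`` /
``Class Left: b0 + AI[region] × w + …``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ParseError
from .lmt import LinearScoreModel, LMTNode, LogisticModelTreeClassifier
from .regions import REGION_NAMES
from .tree import C45TreeClassifier, TreeNode

SCHEMA = "petasym-model/1"


# -- to dict -----------------------------------------------------------


def _tree_to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {"class": node.leaf_class, "n": node.n, "counts": node.class_counts}
    return {"feature": node.feature, "threshold": node.threshold,
            "le": _tree_to_dict(node.le), "gt": _tree_to_dict(node.gt)}


def _lmt_to_dict(node: LMTNode) -> dict:
    if node.is_leaf:
        return {"intercept": node.model.intercept, "coef": node.model.coef}
    return {"feature": node.feature, "threshold": node.threshold,
            "le": _lmt_to_dict(node.le), "gt": _lmt_to_dict(node.gt)}


def model_to_dict(model) -> dict:
    """Serialize a fitted classifier or bare model object."""
    if isinstance(model, C45TreeClassifier):
        return {"schema": SCHEMA, "kind": "c45",
                "classes": [str(c) for c in model.classes_],
                "model": _tree_to_dict(model.tree_)}
    if isinstance(model, TreeNode):
        return {"schema": SCHEMA, "kind": "c45", "classes": ["Left", "Right"],
                "model": _tree_to_dict(model)}
    if isinstance(model, LogisticModelTreeClassifier):
        root = model.tree_ if isinstance(model.tree_, LMTNode) else LMTNode(model=model.model_)
        return {"schema": SCHEMA, "kind": "lmt",
                "classes": [str(c) for c in model.classes_],
                "model": _lmt_to_dict(root)}
    if isinstance(model, LinearScoreModel):
        return {"schema": SCHEMA, "kind": "lmt", "classes": list(model.classes),
                "model": {"intercept": model.intercept, "coef": dict(model.coef)}}
    if isinstance(model, LMTNode):
        return {"schema": SCHEMA, "kind": "lmt", "classes": ["Left", "Right"],
                "model": _lmt_to_dict(model)}
    raise ParseError(f"cannot serialize object of type {type(model).__name__}")


# -- from dict ---------------------------------------------------------


def _check_feature(name, known) -> str:
    if not isinstance(name, str) or name not in known:
        raise ParseError(f"unknown feature name {name!r}")
    return name


def _tree_from_dict(d: dict, classes, known) -> TreeNode:
    if not isinstance(d, dict):
        raise ParseError("tree node must be an object")
    if "class" in d:
        if d["class"] not in classes:
            raise ParseError(f"unknown leaf class {d['class']!r}")
        return TreeNode(leaf_class=d["class"], n=int(d.get("n", 0)),
                        class_counts=dict(d.get("counts", {})))
    try:
        return TreeNode(feature=_check_feature(d["feature"], known),
                        threshold=float(d["threshold"]),
                        le=_tree_from_dict(d["le"], classes, known),
                        gt=_tree_from_dict(d["gt"], classes, known))
    except KeyError as exc:
        raise ParseError(f"tree node missing field {exc}") from exc


def _lmt_from_dict(d: dict, classes, known) -> LMTNode:
    if not isinstance(d, dict):
        raise ParseError("model node must be an object")
    if "intercept" in d:
        coef = {_check_feature(f, known): float(w) for f, w in d.get("coef", {}).items()}
        return LMTNode(model=LinearScoreModel(float(d["intercept"]), coef,
                                              classes=tuple(classes)))
    try:
        return LMTNode(feature=_check_feature(d["feature"], known),
                       threshold=float(d["threshold"]),
                       le=_lmt_from_dict(d["le"], classes, known),
                       gt=_lmt_from_dict(d["gt"], classes, known))
    except KeyError as exc:
        raise ParseError(f"model node missing field {exc}") from exc


def model_from_dict(d: dict, known_features=REGION_NAMES):
    """Parse a serialized model into a fitted classifier object."""
    if not isinstance(d, dict) or d.get("schema") != SCHEMA:
        raise ParseError(f"expected schema {SCHEMA!r}")
    classes = d.get("classes")
    if not isinstance(classes, list) or len(classes) != 2:
        raise ParseError("model must declare exactly two classes")
    known = set(known_features)
    if d.get("kind") == "c45":
        tree = _tree_from_dict(d["model"], classes, known)
        used = sorted({n.feature for n in _walk_tree(tree) if n.feature})
        return C45TreeClassifier.from_tree(tree, classes=classes, feature_names=used)
    if d.get("kind") == "lmt":
        root = _lmt_from_dict(d["model"], classes, known)
        clf = LogisticModelTreeClassifier()
        clf.classes_ = np.asarray(classes, dtype=object)
        names = set()
        for leaf in root.leaves():
            names |= set(leaf.model.coef)
        for node in _walk_lmt(root):
            if node.feature:
                names.add(node.feature)
        clf.feature_names_in_ = np.asarray(sorted(names), dtype=object)
        clf.n_features_in_ = len(clf.feature_names_in_)
        clf.tree_ = root
        clf.model_ = root.model if root.is_leaf else root
        clf.n_boost_iter_ = 0
        return clf
    raise ParseError(f"unknown model kind {d.get('kind')!r}")


def _walk_tree(node: TreeNode):
    yield node
    if not node.is_leaf:
        yield from _walk_tree(node.le)
        yield from _walk_tree(node.gt)


def _walk_lmt(node: LMTNode):
    yield node
    if not node.is_leaf:
        yield from _walk_lmt(node.le)
        yield from _walk_lmt(node.gt)


# -- JSON file round trip ----------------------------------------------


def save_model(model, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2, ensure_ascii=False))


def load_model(path: str | Path, known_features=REGION_NAMES):
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed model JSON: {exc}") from exc
    return model_from_dict(d, known_features)


# -- human-readable rules ----------------------------------------------


def _fmt(v: float) -> str:
    return f"{v:g}"


def _render_tree(node: TreeNode, indent: str = "") -> list[str]:
    if node.is_leaf:
        return [f"{indent}: {node.leaf_class}"]
    lines = []
    for op, child in (("≤", node.le), ("> ", node.gt)):
        head = f"{indent}AI[{node.feature}] {op.strip()} {_fmt(node.threshold)}"
        if child.is_leaf:
            lines.append(f"{head}: {child.leaf_class}")
        else:
            lines.append(head)
            lines.extend(_render_tree(child, indent + "|   "))
    return lines


def _render_linear(model: LinearScoreModel) -> list[str]:
    def side(sign: float, cls: str) -> str:
        terms = [f"{_fmt(sign * model.intercept)}"]
        terms += [f"AI[{f}] × {_fmt(sign * w)}" for f, w in model.coef.items()]
        return f"Class {cls}: " + " + ".join(terms)
    return [side(-1.0, model.classes[0]), side(+1.0, model.classes[1])]


def render_rules(model) -> str:
    """Printed-rule rendering of any supported model object."""
    if isinstance(model, C45TreeClassifier):
        model = model.tree_
    if isinstance(model, LogisticModelTreeClassifier):
        model = model.tree_
    if isinstance(model, TreeNode):
        return "\n".join(_render_tree(model))
    if isinstance(model, LinearScoreModel):
        return "\n".join(_render_linear(model))
    if isinstance(model, LMTNode):
        if model.is_leaf:
            return "\n".join(_render_linear(model.model))
        lines = []
        for op, child in (("≤", model.le), ("> ", model.gt)):
            lines.append(f"AI[{model.feature}] {op.strip()} {_fmt(model.threshold)}:")
            sub = render_rules(child)
            lines.extend("    " + ln for ln in sub.splitlines())
        return "\n".join(lines)
    raise ParseError(f"cannot render object of type {type(model).__name__}")
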