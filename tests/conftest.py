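import numpy as np
import pytest

from peakmil import (
    EncoderConfig,
    InstanceConfig,
    MILModel,
    SyntheticSpec,
    TrainConfig,
    generate,
    split_bags,
    train,
)
from peakmil.workflows import run_synthetic_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def toy_model():
    """A small model trained for a few epochs on short synthetic bags.

    Cheap to build; used wherever a trained (not necessarily well
    generalizing) differentiable model is needed, e.g. integrated-gradients
    completeness checks.
    """
    spec = SyntheticSpec(n_pos=60, n_neg=60, min_length=100, max_length=200, seed=7)
    bags, truth = generate(spec)
    inst_cfg = InstanceConfig()
    tr, va, te = split_bags(bags, rng=np.random.default_rng(7))
    model = MILModel(EncoderConfig(), pooling="gated", seed=7)
    model, history = train(model, tr, va, TrainConfig(epochs=20, seed=7), inst_cfg)
    return {
        "model": model,
        "bags": bags,
        "test_bags": te,
        "inst_cfg": inst_cfg,
        "history": history,
        "spec": spec,
    }


@pytest.fixture(scope="session")
def e2e_run():
    """The full synthetic recovery experiment at default conditions.

    200+200 bags, seed 42, 30 training epochs; shared across the acceptance
    and attribution tests so the model is trained once per session.
    """
    return run_synthetic_experiment(42)


@pytest.fixture(scope="session")
def confident_attribution_case(e2e_run):
    """A (model, x, x_ref) triple where attribution completeness is testable.

    Picks the first centered-site sequence the trained model calls positive
    with high confidence while its dinucleotide-shuffled reference scores
    low: relative completeness error is only meaningful when
    |F(x) - F(x_ref)| is substantial (a shuffled reference can retain enough
    dinucleotide composition to score positive itself).
    """
    from peakmil.attribution import dinuc_shuffle
    from peakmil.bagging import encode_onehot, make_instances
    from peakmil.synthetic_data import SyntheticSpec, make_centered_eval
    from peakmil.bagging import Bag

    model = e2e_run["model"]
    inst_cfg = InstanceConfig()
    centered = make_centered_eval(e2e_run["truth"], SyntheticSpec(seed=42))
    for item in centered:
        bag = Bag(id=item.site_id, sequence=item.sequence, label=1)
        iset = make_instances(bag, inst_cfg)
        p_x, _ = model.predict(iset.instances[None], iset.mask[None])
        ref_seq = dinuc_shuffle(bag.sequence, np.random.default_rng(0))
        rset = make_instances(Bag(id="ref", sequence=ref_seq, label=1), inst_cfg)
        p_ref, _ = model.predict(rset.instances[None], rset.mask[None])
        if p_x[0] >= 0.9 and abs(p_x[0] - p_ref[0]) >= 0.5:
            return {
                "model": model,
                "x": encode_onehot(bag.sequence),
                "x_ref": encode_onehot(ref_seq),
                "inst_cfg": inst_cfg,
            }
    raise RuntimeError("no confident attribution case found")
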