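import numpy as np
import pandas as pd
from omicweave.containers import OmicsDataset, make_feature_meta


def make_dataset(
    values,
    feature_ids=None,
    sample_ids=None,
    groups=None,
    log_transformed=True,
    layer_name="test",
    **sample_cols,
):
    """Small OmicsDataset helper for unit tests."""
    values = np.asarray(values, float)
    n_feat, n_samp = values.shape
    feature_ids = feature_ids or [f"f{i}" for i in range(n_feat)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samp)]
    groups = groups or ["A"] * n_samp
    meta = make_feature_meta(feature_ids)
    sample_meta = pd.DataFrame(
        {"group": groups, **sample_cols}, index=pd.Index(sample_ids, name="sample_id")
    )
    return OmicsDataset(
        layer_name=layer_name,
        intensities=pd.DataFrame(values, index=meta.index, columns=sample_meta.index),
        feature_meta=meta,
        sample_meta=sample_meta,
        log_transformed=log_transformed,
    )
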