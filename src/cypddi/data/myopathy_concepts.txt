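# Myopathy outcome concept set (one concept name per line; editable).
# Mirrors the clinical manifestations used to define the myopathy phenotype.
Myalgia and myositis
Myalgia and myositis, unspecified
Myositis
Polymyositis
Myoglobinuria
Rhabdomyolysis
Muscle weakness
Muscle weakness (generalized)
Myopathy, unspecified
Other myopathies
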