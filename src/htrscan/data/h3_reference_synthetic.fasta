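>h3_mature_reference_synthetic
ALRKQVERKHLVNMRMWRVKTVAQEQKWHSTCQTGKAFQYYNSKCTQMPRIDGLDVEYQA
EYLVNKEKCCRKPLYELWNELAAWRYHQFLNRWYAYRAQVGFRHVYDLGLEYDIMYISNS
FPTQMWQDIMLAMFS
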