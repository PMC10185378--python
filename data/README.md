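# Study data

The published study's mean-rating table (240 actions x 23 bipolar
characteristics, averaged over ~10 raters per characteristic) is deposited
publicly at https://osf.io/4vew8/. To run the study-data checks, download it
and save it here as `osf_mean_ratings.csv` in the wide "matrix dialect":
first column = action id, remaining columns = the 23 characteristic labels
(e.g. "Weak - Powerful"), cell values = mean ratings on the 1-9 scale.

No study data is redistributed with this package; everything else in the
test suite and the acceptance script runs on synthetic studies generated by
`actionspace.synthetic`.
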