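tissue	transcript
adrenal gland	TCONS_00223090
adrenal gland	TCONS_00141903
adrenal gland	TCONS_00214308
adrenal gland	TCONS_00040537
adrenal gland	TCONS_00119463
adrenal gland	TCONS_00093659
adrenal gland	TCONS_00180358
adrenal gland	TCONS_00072894
adrenal gland	TCONS_00034840
adrenal gland	TCONS_00164459
adrenal gland	TCONS_00027608
adrenal gland	TCONS_00015370
adrenal gland	TCONS_00127543
hypothalamus	TCONS_00222966
hypothalamus	TCONS_00128697
hypothalamus	TCONS_00016951
hypothalamus	TCONS_00065862
hypothalamus	TCONS_00106598
hypothalamus	TCONS_00157676
hypothalamus	TCONS_00083779
hypothalamus	TCONS_00139694
hypothalamus	TCONS_00141903
liver	TCONS_00106745
liver	TCONS_00130767
liver	TCONS_00061987
liver	TCONS_00025987
liver	TCONS_00128934
liver	TCONS_00157869
liver	TCONS_00222578
liver	TCONS_00222972
liver	TCONS_00188391
liver	TCONS_00222966
muscle	TCONS_00140963
muscle	TCONS_00223154
muscle	TCONS_00128551
muscle	TCONS_00032445
muscle	TCONS_00095545
muscle	TCONS_00000271
muscle	TCONS_00141506
muscle	TCONS_00051404
muscle	TCONS_00120014
muscle	TCONS_00033623
muscle	TCONS_00203516
muscle	TCONS_00051406
muscle	TCONS_00167041
muscle	TCONS_00190543
pituitary gland	TCONS_00116172
pituitary gland	TCONS_00032383
pituitary gland	TCONS_00105367
pituitary gland	TCONS_00077897
pituitary gland	TCONS_00157315
pituitary gland	TCONS_00202013
pituitary gland	TCONS_00062811
pituitary gland	TCONS_00009194
pituitary gland	TCONS_00131281
pituitary gland	TCONS_00150705
pituitary gland	TCONS_00170772
pituitary gland	TCONS_00116008
pituitary gland	TCONS_00168127
pituitary gland	TCONS_00188529
pituitary gland	TCONS_00059814
pituitary gland	TCONS_00223090
pituitary gland	TCONS_00141903
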