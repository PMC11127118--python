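# Synthetic reconstruction of the RAI-ICD parameter code map.
# NOT a transcription of the instrument's official (licensed) code list:
# clinically plausible ICD-10-CM families were assembled per parameter,
# matching the official list's structure and total size (323 distinct codes).
# Patterns of <=4 characters match all descendant codes (prefix mode);
# longer patterns match exactly.

version: synthetic-v1
parameters:
  weight_loss:
    - R634
    - R64
    - E40
    - E41
    - E42
    - E43
    - E440
    - E441
    - E45
    - E46
  poor_appetite:
    - R630
  congestive_heart_failure:
    - I110
    - I130
    - I132
    - I501
    - I5020
    - I5021
    - I5022
    - I5023
    - I5030
    - I5031
    - I5032
    - I5033
    - I5040
    - I5041
    - I5042
    - I5043
    - I50810
    - I50811
    - I50812
    - I50813
    - I50814
    - I5082
    - I5083
    - I5084
    - I5089
    - I509
  shortness_of_breath:
    - R0600
    - R0602
    - R0603
    - R0609
  kidney_failure:
    - N184
    - N185
    - N186
    - I120
    - I1311
    - Z992
    - Z4931
    - Z4932
  cognitive_decline:
    - F0150
    - F0151
    - F0280
    - F0281
    - F0390
    - F0391
    - G300
    - G301
    - G308
    - G309
    - G3101
    - G3109
    - G311
    - G3184
    - R4181
  functional_status_partial:
    - Z741
    - Z7409
    - Z743
    - R260
    - R261
    - R262
    - R2689
    - R269
    - R531
    - R5381
  functional_status_total:
    - Z7401
    - R532
    - Z9911
    - Z993
    - Z9981
cancer:
  severe:
    - C153
    - C154
    - C155
    - C159
    - C160
    - C161
    - C162
    - C163
    - C164
    - C165
    - C166
    - C167
    - C168
    - C169
    - C220
    - C221
    - C222
    - C223
    - C224
    - C227
    - C228
    - C229
    - C23
    - C240
    - C241
    - C248
    - C249
    - C250
    - C251
    - C252
    - C253
    - C254
    - C257
    - C258
    - C259
    - C260
    - C261
    - C269
    - C33
    - C340
    - C341
    - C342
    - C343
    - C348
    - C349
    - C384
    - C450
    - C451
    - C452
    - C459
    - C480
    - C481
    - C482
    - C488
    - C700
    - C701
    - C709
    - C710
    - C711
    - C712
    - C713
    - C714
    - C715
    - C716
    - C717
    - C718
    - C719
    - C720
    - C721
    - C725
    - C729
    - C740
    - C741
    - C749
    - C760
    - C761
    - C762
    - C763
    - C764
    - C768
    - C770
    - C771
    - C772
    - C773
    - C774
    - C775
    - C778
    - C779
    - C780
    - C781
    - C782
    - C783
    - C784
    - C785
    - C786
    - C787
    - C788
    - C790
    - C791
    - C792
    - C793
    - C794
    - C795
    - C796
    - C797
    - C798
    - C799
    - C800
    - C801
    - C809
    - C920
    - C921
    - C922
    - C923
    - C924
    - C925
    - C926
    - C927
    - C928
    - C929
    - C930
    - C931
    - C939
    - C940
    - C942
    - C946
    - C948
    - C950
    - C951
    - C959
  moderate:
    - C00
    - C01
    - C02
    - C03
    - C04
    - C05
    - C06
    - C07
    - C08
    - C09
    - C10
    - C11
    - C12
    - C13
    - C14
    - C17
    - C180
    - C181
    - C182
    - C183
    - C184
    - C185
    - C186
    - C187
    - C188
    - C189
    - C19
    - C20
    - C21
    - C30
    - C31
    - C32
    - C37
    - C38
    - C39
    - C40
    - C41
    - C46
    - C47
    - C49
    - C4A
    - C51
    - C52
    - C530
    - C531
    - C538
    - C539
    - C561
    - C562
    - C563
    - C569
    - C57
    - C58
    - C63
    - C65
    - C66
    - C670
    - C671
    - C672
    - C673
    - C674
    - C675
    - C676
    - C677
    - C678
    - C679
    - C68
    - C7A
    - C7B
    - C81
    - C82
    - C83
    - C84
    - C85
    - C86
    - C88
    - C900
    - C901
    - C902
    - C910
    - C911
    - C912
    - C913
    - C914
    - C915
    - C919
    - C960
    - C962
    - C969
  mild:
    - C43
    - C44
    - C500
    - C501
    - C502
    - C503
    - C504
    - C505
    - C506
    - C508
    - C509
    - C540
    - C541
    - C542
    - C543
    - C548
    - C549
    - C55
    - C60
    - C61
    - C62
    - C64
    - C69
    - C73
    - C75
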