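roi_id,name,subnetwork,is_hippocampus,is_stg_control,voxels_total,voxels_in_mask
ROI001,Hipp_rostral_L,other,1,0,239,214
ROI002,Hipp_rostral_R,other,1,0,310,246
ROI003,Hipp_caudal_L,other,1,0,641,604
ROI004,Hipp_caudal_R,other,1,0,598,403
ROI005,STG_A22c_L,other,0,1,603,355
ROI006,STG_A22c_R,other,0,1,215,169
ROI007,DMN_region_01,DMN,0,0,282,219
ROI008,DMN_region_02,DMN,0,0,348,277
ROI009,DMN_region_03,DMN,0,0,870,522
ROI010,DMN_region_04,DMN,0,0,203,158
ROI011,DMN_region_05,DMN,0,0,349,255
ROI012,DMN_region_06,DMN,0,0,688,547
ROI013,DMN_region_07,DMN,0,0,702,618
ROI014,DMN_region_08,DMN,0,0,372,349
ROI015,DMN_region_09,DMN,0,0,810,775
ROI016,DMN_region_10,DMN,0,0,323,253
ROI017,DMN_region_11,DMN,0,0,448,421
ROI018,DMN_region_12,DMN,0,0,704,633
ROI019,DMN_region_13,DMN,0,0,478,306
ROI020,DMN_region_14,DMN,0,0,593,448
ROI021,DMN_region_15,DMN,0,0,201,154
ROI022,DMN_region_16,DMN,0,0,661,452
ROI023,DMN_region_17,DMN,0,0,407,365
ROI024,DMN_region_18,DMN,0,0,497,493
ROI025,DMN_region_19,DMN,0,0,583,550
ROI026,DMN_region_20,DMN,0,0,664,655
ROI027,DMN_region_21,DMN,0,0,376,343
ROI028,Visual_region_01,visual,0,0,375,331
ROI029,Visual_region_02,visual,0,0,402,280
ROI030,Visual_region_03,visual,0,0,744,514
ROI031,Visual_region_04,visual,0,0,872,515
ROI032,Visual_region_05,visual,0,0,886,720
ROI033,Visual_region_06,visual,0,0,271,243
ROI034,Visual_region_07,visual,0,0,771,602
ROI035,Visual_region_08,visual,0,0,504,441
ROI036,Visual_region_09,visual,0,0,269,152
ROI037,Visual_region_10,visual,0,0,629,615
ROI038,Visual_region_11,visual,0,0,335,249
ROI039,Visual_region_12,visual,0,0,184,166
ROI040,Visual_region_13,visual,0,0,465,355
ROI041,Visual_region_14,visual,0,0,235,143
ROI042,Visual_region_15,visual,0,0,501,491
ROI043,Visual_region_16,visual,0,0,677,436
ROI044,Visual_region_17,visual,0,0,873,829
ROI045,Assoc_region_01,other,0,0,567,389
ROI046,Assoc_region_02,other,0,0,615,368
ROI047,Assoc_region_03,other,0,0,388,296
ROI048,Assoc_region_04,other,0,0,403,361
ROI049,Assoc_region_05,other,0,0,853,608
ROI050,Assoc_region_06,other,0,0,293,266
ROI051,Assoc_region_07,other,0,0,317,307
ROI052,Assoc_region_08,other,0,0,197,175
ROI053,Assoc_region_09,other,0,0,363,314
ROI054,Assoc_region_10,other,0,0,573,489
ROI055,Assoc_region_11,other,0,0,824,660
ROI056,Assoc_region_12,other,0,0,885,683
ROI057,Assoc_region_13,other,0,0,291,220
ROI058,Assoc_region_14,other,0,0,817,637
ROI059,Assoc_region_15,other,0,0,388,293
ROI060,Assoc_region_16,other,0,0,186,124
ROI061,Assoc_region_17,other,0,0,201,166
ROI062,Assoc_region_18,other,0,0,859,740
ROI063,Assoc_region_19,other,0,0,262,191
ROI064,Assoc_region_20,other,0,0,715,690
ROI065,Assoc_region_21,other,0,0,669,390
ROI066,Assoc_region_22,other,0,0,598,532
ROI067,Assoc_region_23,other,0,0,299,254
ROI068,Assoc_region_24,other,0,0,191,128
ROI069,Assoc_region_25,other,0,0,510,498
ROI070,Assoc_region_26,other,0,0,376,374
ROI071,Assoc_region_27,other,0,0,512,429
ROI072,Assoc_region_28,other,0,0,226,192
ROI073,Assoc_region_29,other,0,0,886,591
ROI074,Assoc_region_30,other,0,0,537,466
ROI075,Assoc_region_31,other,0,0,266,266
ROI076,Assoc_region_32,other,0,0,611,389
ROI077,Assoc_region_33,other,0,0,888,611
ROI078,Assoc_region_34,other,0,0,357,313
ROI079,Assoc_region_35,other,0,0,455,339
ROI080,Assoc_region_36,other,0,0,242,181
ROI081,Assoc_region_37,other,0,0,843,548
ROI082,Assoc_region_38,other,0,0,512,508
ROI083,Assoc_region_39,other,0,0,505,375
ROI084,Assoc_region_40,other,0,0,376,249
ROI085,Assoc_region_41,other,0,0,571,529
ROI086,Assoc_region_42,other,0,0,861,658
ROI087,Assoc_region_43,other,0,0,465,461
ROI088,Assoc_region_44,other,0,0,851,607
ROI089,Assoc_region_45,other,0,0,458,402
ROI090,Assoc_region_46,other,0,0,874,547
ROI091,Assoc_region_47,other,0,0,873,638
ROI092,Assoc_region_48,other,0,0,195,112
ROI093,Assoc_region_49,other,0,0,486,332
ROI094,Assoc_region_50,other,0,0,508,508
ROI095,Assoc_region_51,other,0,0,610,532
ROI096,Assoc_region_52,other,0,0,550,374
ROI097,Assoc_region_53,other,0,0,493,364
ROI098,Assoc_region_54,other,0,0,835,626
ROI099,Assoc_region_55,other,0,0,835,530
ROI100,Assoc_region_56,other,0,0,864,490
ROI101,Assoc_region_57,other,0,0,724,581
ROI102,Assoc_region_58,other,0,0,830,728
ROI103,Assoc_region_59,other,0,0,531,493
ROI104,Assoc_region_60,other,0,0,717,609
ROI105,Assoc_region_61,other,0,0,259,164
ROI106,Assoc_region_62,other,0,0,760,645
ROI107,Assoc_region_63,other,0,0,882,638
ROI108,Assoc_region_64,other,0,0,567,567
ROI109,Assoc_region_65,other,0,0,576,353
ROI110,Assoc_region_66,other,0,0,240,208
ROI111,Assoc_region_67,other,0,0,897,495
ROI112,Assoc_region_68,other,0,0,595,566
ROI113,Assoc_region_69,other,0,0,811,559
ROI114,Assoc_region_70,other,0,0,892,699
ROI115,Assoc_region_71,other,0,0,500,492
ROI116,Assoc_region_72,other,0,0,830,613
ROI117,Assoc_region_73,other,0,0,376,307
ROI118,Assoc_region_74,other,0,0,649,429
ROI119,Assoc_region_75,other,0,0,370,218
ROI120,Assoc_region_76,other,0,0,845,476
ROI121,Assoc_region_77,other,0,0,218,174
ROI122,Assoc_region_78,other,0,0,706,517
ROI123,Assoc_region_79,other,0,0,826,793
ROI124,Assoc_region_80,other,0,0,815,744
ROI125,Assoc_region_81,other,0,0,868,729
ROI126,Assoc_region_82,other,0,0,480,401
ROI127,Assoc_region_83,other,0,0,576,514
ROI128,Assoc_region_84,other,0,0,607,568
ROI129,Assoc_region_85,other,0,0,187,108
ROI130,Assoc_region_86,other,0,0,233,132
ROI131,Assoc_region_87,other,0,0,570,441
ROI132,Assoc_region_88,other,0,0,371,269
ROI133,Assoc_region_89,other,0,0,421,242
ROI134,Assoc_region_90,other,0,0,368,254
ROI135,Assoc_region_91,other,0,0,481,434
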