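participant_id,wallet,envelope,glasses,phone,wipe_counter,out_of_car,stabilize_paper,stabilize_dishes,carry_cup,carry_bags,chair_armrests,pull_chair,hold_book,keyboard,mouse,socks,shoes,shoe_laces,sleeve,face_cream,wash_face,dry_face,comb_hair,button_shirt,zip_coat,peel_fruit,fork_spoon
A01,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
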